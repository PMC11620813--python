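# Methods

## Data model and counting rules

The atomic observation is the **use report**: a tuple (informant, taxon,
ailment, part, preparation, administration).  Identical tuples are
collapsed on load — one use report is one distinct tuple.  From the
report table the package counts, for the survey's N informants:

* **FC** (per species) and **fc** (per family): *distinct informants*
  citing the species / any species of the family, regardless of how many
  ailments each mentions;
* **U** (per species) and **Nur** (per ailment category): *use reports*,
  so an informant citing one plant for two ailments contributes one
  citation but two reports;
* **Nt** (per category): distinct species cited in the category.

This is the only pair of counting rules under which UV can exceed RFC
(e.g. *Ficus thonningii*: RFC 0.164, UV 0.455 in the packaged survey),
which published tables require.  The converse, U ≥ FC, is **not**
enforced on loaded data: the packaged survey itself contains nine species
with UV < RFC, so real tables violate "at least one report per citing
informant".  The synthetic generator, by contrast, guarantees U ≥ FC by
construction (see below).

Ailment labels are matched case- and whitespace-insensitively with
singular/plural folding ("coughs" ≡ "cough"; labels ending in -ss/-sis/-us
such as *tuberculosis* are never folded).  A label missing from the
ailment→category map is an error, never a silent drop.

Taxon names are canonicalized to `Genus epithet`: authorship, basionym
parentheses, hybrid signs and infrageneric markers are stripped; the
operation is idempotent.  No synonym resolution is attempted — checklist
intersection is exact on canonical binomials.

## Index formulas and degenerate inputs

RFC = FC/N, UV = U/N, FIV = fc/N×100, ICF = (Nur−Nt)/(Nur−1),
JI = c/(a+b+c)×100.  N = 0 raises an undefined-denominator error; counts
exceeding their bound (FC > N, Nt > Nur, c > min(a,b)) raise consistency
errors.  ICF for a category with a single use report (Nur = 1) is
**undefined and raised as an error**, not reported as 0: silent zeros
would bias category rankings built on sparse categories.  In the
dataset-level table builder such categories are retained with a
`degenerate` flag and an NA ICF.

PPV has two documented modes because the literal formula and published
values follow different denominators.  `use_report` mode implements
RU(part)/ΣRU over reports (shares sum to 100); `species` mode divides the
number of species using the part by the species total (shares may exceed
100 since species contribute several parts) and is the default, because
the published part percentages of the packaged survey equal species
fractions of 42 (bark 9/42 = 21.4%, whole plant 3/42 = 7.1%).

The JI denominator a+b+c is kept exactly as the comparison tables use it
(each study total already includes the shared species).  It reproduces
every published comparison row; the classical c/(a+b−c) does not, and is
offered only behind an explicit option.

## Rounding at the reporting boundary

All computation runs at full float precision; rounding happens only when
values are displayed or written.  RFC, UV and ICF round half-up to 3
decimals; percentages to 1 decimal; JI to 1 decimal.  FIV is displayed as
an integer through a **two-stage chain**: half-up to one decimal, then to
an integer.  The chain is deliberate: legacy spreadsheet tables format the
percentage at one decimal and round the displayed value again, so
fc/N×100 = 25.4545… prints as 26.  In the packaged survey exactly the four
families whose percentage ends in .4545 (fc = 3, 14, 25, 36 at N = 55)
print this way, and the chain reproduces all 28 published FIV cells;
single-stage rounding cannot reach four of them.  RFC/UV keep the
single-stage rule — a chain at 4→3 decimals would corrupt the four
published 0.145 cells (8/55 = 0.1454545…).

## The packaged fixture

The fixture transcribes the species-attribute table of a Tanzanian
respiratory-ailment survey verbatim (42 species, 28 families) together
with **inverted integer counts**: raw per-informant reports were never
published, so FC = round(RFC×55), U = round(UV×55), fc = round(FIV×55/100)
were reconstructed from the printed indices and verified to re-round to
every printed cell.  Internal cross-checks hold throughout: every family
satisfies max FC ≤ fc ≤ ΣFC (singleton families give fc = FC exactly).
The per-category (Nur, Nt) integers, the cross-study totals and the
demographic margins are carried as printed.

Known source-table inconsistencies are recorded in the fixture metadata
rather than repaired silently:

* four ailment entries (three "cold", one "throat infection") are omitted
  from the species table because no total label→category map reproduces
  the published per-category species counts with them present;
* the bare part code "S" of *Syzygium aromaticum* is encoded as
  `flower` (the clove of commerce is the flower bud; the table's key
  defines S only as the shrub life form);
* the parts column yields 16 root and 3 flower species where the text
  prints 15 (35.7%) and 2 (4.8%); the verbatim column is kept;
* per-species reports sum to 667 while per-category reports sum to 733;
  both tables are kept as printed (they are independent inversions);
* the survey text rounds two FIV values (5%, 7%) single-stage where its
  own table prints 6 and 9.

The informant table contains 55 synthetic rows whose marginal counts per
demographic attribute equal the published profile exactly; the joint
distribution is an arbitrary seeded assignment, because only margins were
published.  The use-report file is header-only.  Consequently the
fixture's published group means (e.g. gender t = 1.761, p = 0.084) are
*calibration targets for the generator*, not reproducible quantities.

## Synthetic survey generator

Informant *i* cites species *s* with probability min(1, m_i·p_s),
independently across informants and species; m_i is the product of
knowledge multipliers attached to the informant's demographic groups.  A
citing informant files one report per ailment category *k* of the species
with probability q_{s,k}; if all category draws fail one report is forced
for the species' first category, so every citation yields at least one
report.  Parts, preparations and administration routes are drawn
uniformly from the species' recorded codes.  There is no informant-level
random effect and no informant co-learning; the structure is the simplest
one consistent with the indices, and passing tests therefore demonstrate
correct counting and calibration, not realism of informant behaviour.

Demographic groups are assigned with exact marginal counts (largest
remainder) and a seeded shuffle, so group sizes are deterministic.  All
randomness derives from one root seed: demographic streams use
`SeedSequence(seed, spawn_key=(0, j))`, informant *i*'s citation stream
`spawn_key=(1, i)` — generation is order-independent and byte-identical
across runs.

Calibration inverts a published index table: p_s = RFC_s, and q solves
kq + (1−q)^k = U_s/FC_s (the expectation including the forced report; the
ratio is clipped into [1, k]).  The default Urambo configuration
additionally carries age-group knowledge multipliers proportional to the
published group means, normalised so the informant-weighted mean
multiplier is exactly 1; with the largest multiplier (1.252) times the
largest citation probability (0.655) below 1, no clipping occurs and
E[RFC] per species remains exactly p_s.

## Demographic knowledge comparisons

Knowledge per informant is scored as *distinct species cited* (published
tables never define their per-informant count; report counting is
available via an option).  Two groups are compared with the Welch
unequal-variance t — group sizes in such surveys are highly unbalanced
(45 vs 10 here), making the pooled-variance t inappropriate — more groups
with the one-way F.  P-values are two-sided, closed-form or by label
permutation with the add-one estimator (1+#{|T*|≥|T|})/(1+B).  The
permutation routine sorts the pooled scores and takes group sizes in
descending order before drawing, so the estimate depends only on the
multisets of scores and sizes: swapping group labels or reordering
informants cannot change it.

## Problem sizes used in the checks

The automated checks run the brute-force oracle comparison on 1000 random
surveys of ≤10 informants × ≤6 species; generator recovery over 500
replicate surveys at the study size (n = 55), requiring each species' mean
simulated RFC within 3 Monte-Carlo standard errors of its calibrated p_s;
and the demographic-effect power check over 100 replicate surveys of 300
informants per age group with a 1.5× multiplier, requiring permutation
p < 0.01 (10,000 permutations) in ≥95% of replicates.

## Limitations

* No taxonomic backbone or synonym resolution; name matching is exact
  after canonicalization.
* Conservation categories are input attributes; no Red List queries.
* The generator models neither snowball-sampling bias nor spatial
  structure; its demographic joint distribution is a product of margins.
* Preparation/administration percentages of the source survey match no
  recoverable denominator and carry no reproduction target.
* Fidelity level (FL) is not computed.
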