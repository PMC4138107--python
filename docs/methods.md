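# Methods

## Motif grammar and the competence decision

A classical (class I, cysteine-based, tyrosine-specific) PTP catalytic
domain is modelled as a constellation of ten motifs around the P-loop
cysteine. Competence of a domain is decided purely from the four
active-site motifs; the competence patterns are degenerate residue
expressions shipped as editable data (`src/aedes_ptp/data/motif_definitions.tsv`),
not code:

* **Motif 1 (KNRY loop)** `[KR].{0,2}R.?[YF]` — a basic residue, the
  conserved arginine, and an aromatic (Y or F) within a short span. F is
  deliberately admitted at the aromatic slot: the repertoire contains a
  motif-1 instance with phenylalanine that is nonetheless competent.
* **Motif 8 (WPD loop)** `WPD` — the general-acid aspartate must sit in
  its Trp-Pro context; `WGD` or `WPK` variants are dead.
* **Motif 9 (P-loop / HCX5R)** `HCSAG[IVLM]GR` — the nucleophilic
  cysteine inside the C-x5-R frame *with* the tyrosine-phosphatase-specific
  S-A-G context. A frame without that context (e.g. `HCNEGGGR`) is the
  signature of a pseudo-phosphatase, not an enzyme.
* **Motif 10 (Q loop)** a nine-residue window with glutamine at positions
  2 and 6.

Rules of evaluation: matching is case-insensitive; an empty region is
ABSENT; a region shorter than the pattern span is INACTIVE, not an error
(real repertoires print truncated degenerate motifs); ambiguity codes
B/Z/X may occupy wildcard positions but never satisfy an anchor class —
catalytic competence requires a *confirmed* catalytic residue. These
patterns were chosen to separate exactly the published ACTIVE and INACTIVE
motif instances of the ten-protein repertoire that ships as the regression
fixture (`data/table1_motifs.tsv`); the agreement suite over all of its
printed motif strings and domain verdicts is the primary regression
surface.

The domain verdict is `ACTIVE ⇔ motifs 8 ∧ 9 ∧ 10 all ACTIVE`. Motif 1 is
diagnostic (it distinguishes tyrosine phosphatases from Ser/Thr
phosphatases) but non-gating: the fixture contains an active enzyme whose
KNRY region is missing entirely. The required-motif set is configuration
(`repertoire.REQUIRED_ACTIVE_MOTIFS`).

## Domain scanning

Profile-HMM search is out of scope; domains are found by motif
constellation:

1. **Anchor enumeration.** Candidate P-loop positions are (a) every match
   of the relaxed frame `C.{5}R`, and (b) anchors *inferred by voting*:
   each core-motif (2–7) match proposes `match_start − expected_offset`,
   and ≥3 agreeing proposals (within ±12 residues) define a candidate even
   when no frame exists. The second route matters: a domain whose
   catalytic Cys has mutated to Ser has no C-x5-R frame left, yet must
   still be found and reported with motif 9 INACTIVE.
2. **Window evaluation.** Each motif is searched in a window at its
   expected offset from the anchor ± tolerance (KNRY ≈ 170 residues
   upstream of the catalytic Cys, WPD ≈ 35 upstream, Q loop ≈ 47
   downstream, per the canonical PTP1B-like architecture; all offsets and
   tolerances are registry columns). An active-site motif whose expected
   position falls outside the sequence is ABSENT; present-but-unmatched
   windows are INACTIVE.
3. **Thresholds.** ≥5 of 10 motifs located ⇒ WELL_FORMED. Overlapping
   candidates resolve most-motifs-first, ties to the leftmost (determinism).
   Core-motif clusters (≥2 distinct core motifs, gaps ≤60 residues) outside
   any well-formed constellation and containing no P-loop frame ⇒
   DEGENERATE, all four active-site calls ABSENT.
4. **Boundaries.** 30 residues upstream of the KNRY window (WPD window
   when the KNRY region is absent) to 20 residues past the Q-loop window,
   clipped to the sequence; coordinates are 1-based inclusive in all
   reports. Boundaries are padding heuristics, not an accuracy surface.

Core motifs 2–7 deserve a caveat: no published per-motif sequences exist
for them in this repertoire, so the registry ships *synthetic* consensus
strings (exact 7-mers) at PTP1B-like offsets. They carry no biological
claim; they exist to give the anchor-voting and degenerate-remnant logic a
well-defined, low-false-positive substrate (a 7-mer hits a random position
with probability 20⁻⁷). Users scanning real proteomes should replace them
with empirically derived patterns via `--config`/`MotifRegistry.load`.

## Phylogenetics

Distances come from pairwise global alignments, not a progressive MSA:
Needleman–Wunsch with affine gaps (BLOSUM62; a gap of length L costs
10 + 1·L), percent identity = identical columns / all alignment columns
(gapped columns count in the denominator), distance = 1 − identity/100.
This is a deliberate method substitution — qualitative clusterings, not
exact published tree shapes, are the testable surface. A local
(Smith–Waterman) identity mode is flag-selectable because published
identity percentages often have unstated provenance (global vs local).

Neighbor joining is the classical Saitou–Nei agglomeration: join the pair
minimising `Q(i,j) = (n−2)d(i,j) − r(i) − r(j)`, branch lengths from the
two-point formulas, matrix reduction by
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, three-taxon closed form at the end.
Determinism and degeneracy handling: ties on Q break by lexicographic
taxon-pair order (internal nodes are keyed by their lexicographically
smallest leaf); negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch; reduced distances are floored at
zero. On additive matrices the algorithm recovers the generating topology
and branch lengths exactly (tested), and the test suite cross-checks
topologies against an independent NJ implementation (scikit-bio).
`clade_check(tree, focal, partners, outgroup)` asks whether any edge
bipartition puts focal + partners on one side with no outgroup member.

## Expression quantification

The Pfaffl ratio unifies the comparative ΔΔCt method with per-primer
efficiency correction; at E = 2 both coincide (`mode="classic"` forces
that). Efficiencies are inputs in fold-per-cycle on [1, 2] (an "at least
95% efficient" primer pair means E ≥ 1.95); estimating them from standard
curves is out of scope. Replicates aggregate by the arithmetic mean of Ct
(the geometric mean on the expression scale); there is no outlier
rejection. The standard error uses the delta method on the log ratio:
`Var(ln R) = (ln E_t)² · Var(ΔCt_t) + (ln E_r)² · Var(ΔCt_r)` with each
ΔCt variance the sum of the two replicate-mean variances. The calibrator's
own ratio is exactly 1 by construction.

A note on achievable precision: ΔΔCt is a difference of four replicate
means, so its sampling sd is `2·σ/√n` cycles. With triplicates and
per-well σ = 0.2 that is 0.23 cycles — a ×1.17 multiplicative 1-σ error —
so a ±15% band captures only ~65% of runs; the Monte-Carlo test asserts
exactly that closed-form coverage rather than an optimistic one. Across
the fold (0.5–4) × noise (0.1–0.3) grid the estimator is unbiased (median
relative bias well under 5%, recomputed by `scripts/acceptance.py`).

ANOVA is the classical between/within mean-square F with (k−1, N−k)
degrees of freedom; the t-test is the pooled-variance Student form. Both
delegate to scipy after contract checks, with the all-constant degenerate
cases defined explicitly (F = 0, t = 0, p = 1); for two groups F = t²
holds to machine precision. Tukey's studentized-range post-test is
deliberately not implemented; reports state ANOVA F and p only.

## Synthetic generators: what they emulate, and what they do not

* **Proteomes** (`make_proteome`, `table1_proteome`): random flanks
  (uniform over the 20 residues; composition is configurable) with 0–2
  planted cassettes per protein. A cassette embeds motif instances at the
  canonical offsets; lesions realise intended statuses
  (anchor mutation → INACTIVE; missing KNRY region → ABSENT, which forces
  the domain to the N-terminus; Cys→Ser for the frameless case). Defaults:
  flanks 60–150 residues, domain count probabilities (0.3, 0.5, 0.2),
  60% of planted domains intact. After planting, each active-site window
  is *sanitised*: filler residues that happen to spell an unintended
  pattern hit are resampled (planted residues are never modified), so
  recorded truth is exact by construction, and remains byte-reproducible
  per seed. The repertoire preset plants the published motif strings
  verbatim and gives splice variants of a locus identical sequences, as
  their real domain content is identical.
* **Families** (`make_family`): a root sequence (default 300 residues)
  evolves down a random binary tree (branch lengths U(0.6, 1.4)) by
  per-site substitution with probability `1 − exp(−rate·bl)`,
  rate 0.08/site/unit length — divergences around 10–40%, where
  alignment-based p-distances are still nearly additive and NJ recovery is
  a fair test. Point substitutions only: no indels, no rate heterogeneity,
  no codon structure.
* **qPCR tables** (`make_ct_table`): `Ct = baseline − log_E(fold) + N(0, σ)`
  per well, gene baselines U(18, 26), reference gene fold pinned at 1,
  triplicates by default. No plate effects, no shared sample-level noise
  (wells are independent), no efficiency misspecification.
* **Cages** (`make_cage_table`): eggs ~ Poisson(mean-per-female × females),
  10–15 females per cage.

Because flanks are uniform-random and wells independent, passing tests
demonstrate correctness of the *decision logic and estimators* under
clean, known-truth conditions — not robustness to real proteome
composition bias, homopolymeric stretches, alignment-ambiguous indels, or
correlated qPCR noise.

## Problem sizes and numerical choices

Default verification sizes: 200 proteins for scanner recall/agreement,
1000 random 300-mers for the false-positive bound, 100 families (8 taxa,
300 sites) for tree recovery, ~500 simulations for the ΔΔCt grid, 50–60
random short pairs against the brute-force alignment oracle. Floating
comparisons: alignment scores to 1e-9 of the oracle; ANOVA/t statistics to
1e-10 of hand-computed sums of squares; NJ branch lengths to relative
1e-9 on additive input. All stochastic tests and the acceptance script
derive every stream from one named seed.

## Known limitations

* The competence grammar is fitted to one published repertoire; it is a
  faithful formalisation of that classification, not a trained model, and
  transfers to other genomes only as far as classical-PTP motif
  conservation does.
* Receptor (transmembrane) PTPs and dual-specificity phosphatases are out
  of scope; the grammar would misclassify the latter by design.
* Degenerate-domain boundaries are heuristic; only presence and motif
  statuses are validated against truth.
* Identity-based distances saturate for deep divergences; no correction
  (Poisson, Kimura) is applied, so trees over very distant sequences
  compress internal branches.
* The 53%-identity ortholog comparison against human PTP1B requires
  user-supplied reference sequences (`analysis/03_phylogeny.py
  --reference`); no external sequence data ships with the package.
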