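# aedes-ptp

Sequence-level analysis of the classical protein tyrosine phosphatase (PTP)
repertoire of *Aedes aegypti* — the mosquito vector of dengue and yellow
fever — built for vector-biology groups who want to separate catalytically
active PTP enzymes from pseudo-phosphatase adaptor domains, place them among
characterised human/fly phosphatases, and quantify their expression after a
blood meal.

## What it computes

**Motif-grammar classification.** A classical PTP catalytic domain is
described by ten conserved motifs; four of them carry the active site and
decide competence:

| motif | name | competence pattern | role |
|---|---|---|---|
| 1 | KNRY loop | `[KR] x{0,2} R x? [YF]` | phosphotyrosine recruitment |
| 8 | WPD loop | `WPD` | general-acid aspartate |
| 9 | P-loop (HCX5R) | `HCSAG[IVLM]GR` | nucleophilic cysteine |
| 10 | Q loop | `xQxxxQxxx` | positions the hydrolytic water |

A domain is called **ACTIVE** iff motifs 8, 9 and 10 are all competent
(motif 1 recruits substrate but does not veto catalysis — the repertoire
contains an active enzyme with no KNRY region). Motifs 2–7 form the
structural core and are used only to anchor the domain search: candidate
P-loop positions come from the relaxed `C-x5-R` frame and from core-motif
constellation voting, and a candidate locating ≥5 of the 10 motifs in its
offset windows becomes a well-formed domain. Core-motif clusters with no
P-loop at all are reported as degenerate (pseudo-phosphatase) remnants.

**Phylogenetics.** Pairwise Needleman–Wunsch alignments (BLOSUM62, affine
gaps, open 10 / extend 1) give percent identity
(identical columns / all columns); distances `d = 1 − identity/100` feed a
classical Saitou–Nei neighbor-joining implementation with deterministic
tie-breaking and Kuhner–Felsenstein clamping of negative branch lengths.

**Expression.** Efficiency-corrected relative expression of a target gene
against the rp49 reference and a calibrator condition (Pfaffl form of the
comparative ΔΔCt method):

```
ratio = E_target^(−ΔCt_target) / E_ref^(−ΔCt_ref),   ΔCt = mean Ct(cond) − mean Ct(calibrator)
```

which reduces to `2^(−ΔΔCt)` at perfect efficiency. Standard errors
propagate from replicate ΔCt spread by the delta method. Egg-laying assays
are normalised to eggs per female per cage and compared by one-way ANOVA or
the pooled-variance Student t-test.

**Synthetic ground truth.** Every stage has a generator
(`aedes_ptp.synth`): proteomes with planted domain cassettes and per-motif
intended statuses, sequence families evolved on recorded trees, and qPCR /
egg-count tables with known effects — so the whole pipeline is testable
without any downloads. A packaged preset (`table1_proteome`) plants the
published ten-protein repertoire's motif strings verbatim.

## Worked example

```bash
aedes-ptp simulate --preset table1_fixture --seed 0 --out sim/
aedes-ptp annotate sim/table1_fixture.fasta --out annotated/
```

prints

```
Classical PTP repertoire summary
================================
proteins scanned:                 10
gene loci:                        8
proteins with >=1 active domain:  7
catalytically active genes:       4

Per-gene calls:
  AAEL001046: 0/2 active domains [inactive]
  AAEL001919: 2/2 active domains [ACTIVE]
  AAEL003108: 1/1 active domains [ACTIVE]
  AAEL005492: 1/1 active domains [ACTIVE]
  AAEL008528: 2/4 active domains [ACTIVE]
  AAEL010234: 0/1 active domains [inactive]
  AAEL010914: 0/1 active domains [inactive]
  AAEL011434: 1/1 active domains [EXCLUDED] (dual-specificity MAPK phosphatase ortholog; not a classical PTP)
```

The ten proteins collapse to 8 gene loci carrying 13 PTP domains. Seven
proteins keep at least one catalytically competent domain; AAEL010234 and
AAEL010914 are pseudo-phosphatases (intact architecture, dead active-site
motifs), and AAEL001046's two domains are degenerate remnants. After the
curated exclusion of AAEL011434 (a MAPK-phosphatase ortholog, not a true
classical PTP), 4 gene loci encode active enzymes — AAEL001919 among them,
the PTP1B-like candidate whose expression the `expression` stage tracks.

The numbered drivers under `analysis/` run the same stages as a narrative
(simulate → annotate → phylogeny → expression), writing their tables under
`results/`:

```bash
python analysis/01_simulate_inputs.py --seed 0
python analysis/02_annotate_repertoire.py
python analysis/03_phylogeny.py        # add --reference refs.fasta to score user-supplied domains
python analysis/04_expression.py
```

## Layout

```
src/aedes_ptp/     motifs · domains · repertoire · phylo · expression · synth · cli
analysis/          numbered narrative drivers
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
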