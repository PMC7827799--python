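# conservscape

Conservation-evolution profiling of protein families: empirical-Bayes
per-site evolutionary rates on a multiple sequence alignment, z-normalised
conservation scores and grades, reference-numbered region and residue
reports, family-unique "fingerprint" residues from paired alignments,
clade-stratified degenerate-motif scanning, and painting of scores onto 3D
structures via the PDB B-factor column.

The package was built for analyses in the style of molecular-evolution
studies of cytochrome P450 aromatase (CYP19A1): given a family of homologs
labelled by taxonomic class (mammal, bird, reptile, amphibian, fish,
invertebrate), quantify which residues, substrate recognition sites (SRSs)
and structural elements have been conserved, which conserved residues are
unique to the family rather than shared across the P450 superfamily, and
which kinase consensus motifs (PKA `R-x(1,2)-[ST]-x`, PKG
`[RK](2,3)-x-[ST]-x`) appear in which clades.

## The model

For each alignment column *i*, the evolutionary rate r\_i is treated as a
random effect with a mean-one discrete-gamma prior (K equiprobable
categories r\_1 < … < r\_K from gamma(α, 1/α), Yang's mean method).  Column
likelihoods L\_i(r) are computed by Felsenstein pruning on a neighbor-joining
guide tree (Kimura-corrected protein distances d = −ln(1 − p − p²/5)) under
the JTT amino-acid model calibrated to one expected substitution per site.
The reported raw rate is the empirical-Bayes posterior mean

    r̂_i = Σ_k r_k L_i(r_k) / Σ_k L_i(r_k),

with α fit by maximum likelihood on the same data (bounded search on
log α ∈ [ln 0.05, ln 10]).  Raw rates are z-normalised over all scored
columns — mean 0, population standard deviation 1 — so **lower scores mean
more conserved**, and binned into nine equal-count grades (9 = most
conserved) for structure coloring.

A synthetic-data generator (`conservscape.seqsim`) evolves clade-labelled
alignments on simulated pure-birth trees with *known* per-site rates and
planted clade-restricted motifs, so every stage of the pipeline is testable
against ground truth.

## Worked example

```python
from conservscape import (score_alignment, build_refmap, annotate_score_table,
                          compile_pattern, anchored_clade_presence)
from conservscape.region_fingerprint import Region, region_conservation_percent
from conservscape.seqsim import SimulationConfig, MotifPlant, simulate_dataset

config = SimulationConfig(
    n_taxa=60,
    site_blocks=((30, 0.1), (270, 1.5)),          # 30 conserved sites, 270 background
    motif_plants=(MotifPlant(frozenset({"mammal", "bird"}), 101, "KRRRIST"),),
    seed=7,
)
alignment, tree, clades, truth = simulate_dataset(config)
table = score_alignment(alignment, tree=tree)
refmap = build_refmap(alignment, alignment.ids[0])
annotate_score_table(table, refmap)

print(f"scores: mean={table.scores.mean():+.2e}, sd={table.scores.std():.6f}")
rep = region_conservation_percent(table, refmap, Region("conserved-core", ((1, 30),)))
print(f"{rep.name}: {rep.percent_conserved}% conserved ({rep.n_conserved}/{rep.n_mapped})")
pka = compile_pattern("R-x(1,2)-[ST]-x", name="PKA")
for clade, (frac, n) in sorted(anchored_clade_presence(
        alignment, clades, refmap, pka, (101, 107)).items()):
    print(f"PKA in {clade:12s}: {frac:.2f} (n={n})")
```

prints

```
scores: mean=-1.66e-16, sd=1.000000
conserved-core: 100.0% conserved (30/30)
PKA in amphibian   : 0.00 (n=3)
PKA in bird        : 1.00 (n=1)
PKA in fish        : 0.00 (n=42)
PKA in invertebrate: 0.00 (n=1)
PKA in mammal      : 1.00 (n=11)
PKA in reptile     : 0.00 (n=2)
```

The normalization contract holds exactly (mean 0, sd 1); all 30 sites
simulated at rate 0.1 land in the top conservation grades, and the KRRRIST
peptide planted in mammals and birds is detected by the PKA consensus in
exactly those clades — the per-clade presence style used to report kinase
sites appearing at different evolutionary stages.

A command-line interface mirrors the library
(`conservscape simulate|score|regions|fingerprint|motifs|paint|run`); see
`conservscape --help`.  `conservscape run --config run.yaml` executes the
whole pipeline into an audited run directory (scores.tsv, regions.tsv,
motifs.tsv, fingerprint.tsv, painted.pdb, run.log).

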