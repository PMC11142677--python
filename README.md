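# redqueen

A mechanistic simulator of the intra-genomic Red Queen of recombination
hotspots, for population geneticists studying PRDM9-dependent recombination.

In mammals, the zinc-finger protein PRDM9 designates recombination hotspots
by binding short target motifs. Because double-strand breaks (DSBs) are
repaired by copying the homologous chromosome, "hot" motif variants are
preferentially overwritten by inactive ones — biased gene conversion erodes
every allele's own binding sites (the hotspot conversion paradox). New
*PRDM9* alleles recognizing fresh motifs are then favoured, driving a
perpetual turnover. This package implements the mechanistic version of that
model in which the selective force emerges from meiosis itself: meiosis
succeeds only if at least one DSB falls at a site *symmetrically* bound
(bound on at least one chromatid of the other homolog), which couples an
allele's erosion state to its carriers' fertility, with gene dosage making
homozygotes bind better than heterozygotes (`x = c·y/(1+c·y)`).

The core quantities, in the field's notation: site occupancy
`x = cy/(1+cy)`; symmetric-binding probability of a homozygote
`q = (2⟨x²⟩−⟨x³⟩)/⟨x⟩`; fertility `w = 1−e^{−dq}` with `d` DSBs per
meiosis; haplo-insufficiency `σ = (w_hom−w_hemi)/w_hemi`; PRDM9 diversity
`D = 1/Σf_i²`; erosion rate `dθ/dt = −ρfθ`, `ρ = Nvd/2h`; intrinsic age
`z(t) = ρ∫f dt`; and the regime classifier built on `4Nu` and `σ₀τ`.

## Worked example

Run the published monomorphic configuration (N = 5000, u = 5e-6, v = 5e-5,
h = 400, d = 6, mean affinity 0.2), speed-rescaled by λ = 10:

```python
import redqueen as rq
from redqueen.experiments import preset

cfg = preset("monomorphic_fig3", rescale=10.0,
             generations=10_000, burn_in=2_500, seed=1)
res = rq.run(cfg)
print({k: round(v, 4) for k, v in res.summary.items()
       if k in ("D", "erosion", "q_bar", "w_bar", "tau")})
```

prints (seed 1):

```
{'D': 1.5348, 'erosion': 0.1788, 'q_bar': 0.393, 'w_bar': 0.905, 'tau': 235.4194}
```

meaning: one dominant PRDM9 allele at a time (effective number of alleles
D ≈ 1.5), which on average has lost ~18% of its target sites before being
replaced by a fresh allele roughly every 235 generations; the population's
mean probability that a DSB is symmetric is ~0.39, giving a mean meiosis
success rate of ~0.90. The same run in the control model without the
symmetry requirement (`mode="control_no_symmetry"`) equilibrates at roughly
2.5 times the erosion — the symmetry requirement is what turns erosion
into selection for new alleles.

`res.scalars` holds the per-generation population series, `res.trajectory`
the per-allele records (frequency, θ, mean affinity, q, w).

The same API drives the other published regimes (`polymorphic_fig4`,
`dosage_fig5`, `calibration_row1..7`, `scaling_reference`) and parameter
grids (`redqueen.run_grid`). A thin CLI wraps it:

```
redqueen run --config cfg.yaml --seed 42 --out outdir/
redqueen grid --spec grid.yaml --out griddir/
redqueen meanfield --config cfg.yaml --tau 150
```

`run` writes `scalars.tsv`, `trajectory.tsv`, `summary.json` and a
JSON population checkpoint (`redqueen-population-v1` schema: allele
registry with loci and affinities, plus each haplotype's allele and
inactivated site indices — enough to restart via `Population.from_json`).

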