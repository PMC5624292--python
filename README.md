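# landgen

Landscape genetics of patch-structured populations: does genetic
differentiation between habitat patches track straight-line geography, the
least-cost route through the surrounding land-use mosaic, or the
circuit-theory resistance of the landscape?

The package targets the classic fragmented-habitat design: mtDNA
control-region sequences sampled from a handful of native-forest patches
surrounded by a matrix of farmland, plantations and shrublands. It
provides, as a library + CLI + numbered analysis scripts:

* **Diversity** — per-patch and pooled N, segregating sites S, haplotype
  number Nh, haplotype diversity Hd ± SD (Nei's unbiased estimator) and
  nucleotide diversity π ± SD, after complete-deletion site filtering.
* **Differentiation** — pairwise γ_ST (Nei's haplotype-frequency analogue
  of F_ST, `γ_ST = (H_T − H_S)/H_T`) with Hudson's Snn nearest-neighbour
  permutation test per patch pair.
* **Landscape models** — a land-use raster plus a class → conductance map
  becomes an 8-neighbour transition graph (`t_ij = (c_i + c_j)/2`),
  geodesically corrected; least-cost distances (Dijkstra on costs
  `1/t_ij`), resistance distances (commute time
  `C = vol(G) · R_eff` from the graph Laplacian), and explicit least-cost
  corridors with their land-use composition.
* **Inference** — Mantel permutation tests of γ_ST against the
  isolation-by-distance (IBD), least-cost-path (LCP) and
  isolation-by-resistance (IBR) distance matrices; with 5 patches the
  test enumerates all 120 relabelings (identity + 119 permutations)
  exactly.
* **Synthetic data** — a generator producing class rasters, corridor
  layouts and Wright–Fisher haplotype samples whose gene flow followed an
  `exp(−d_LCP/λ)` kernel, so every stage of the pipeline is testable
  against known ground truth. See `docs/methods.md` for all conventions.

## Worked example

```sh
python analysis/01_simulate_landscape.py   # synthetic scenario + sample
python analysis/02_diversity_tables.py     # diversity + differentiation
python analysis/03_landscape_distances.py  # IBD / LCP / IBR matrices
python analysis/04_model_comparison.py     # Mantel model comparison
python analysis/05_replicate_recovery.py   # 50-replicate recovery check
```

The corridor scenario links five forest patches (73 sequences, 527 bp) in
a zigzag corridor chain, so straight-line distance says nothing about
connectivity. The model comparison (step 04) prints:

```
Sequences: 73; segregating sites S = 44; haplotypes Nh = 22
Pooled Hd = 0.930 ± 0.014; π = 0.009 ± 0.001

IBD: Mantel r = -0.052, p = 0.6167 (119 permutations, exhaustive)
LCP: Mantel r = 0.599, p = 0.0167 (119 permutations, exhaustive)
IBR: Mantel r = 0.622, p = 0.0833 (119 permutations, exhaustive)

Best-supported model at alpha = 0.05: LCP
```

Geography (IBD) carries no signal — as built into the scenario — while
the least-cost model is both strong and significant: the genetic data
recover the corridor structure that actually channelled gene flow. Step
05 repeats this over 50 simulated datasets: `r(LCP) > r(IBD)` in 100% of
replicates, and whenever any model reaches significance it is almost
always LCP. The same stages are available as a CLI
(`landgen simulate|diversity|gammast|snn|landscape|mantel|run-full`).

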