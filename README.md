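# comphot

**Comparative retroviral integration hotspot detection.**

Retroviral gene-transfer vectors (HIV- and MLV-derived in the motivating
application) insert their provirus at non-random genomic positions, and the
two vector families favour different chromatin contexts. `comphot` finds
*comparative hotspots*: genomic segments where the integration-site
densities of two vectors differ — not where either vector is merely
frequent. It is aimed at labs analysing integration-site libraries
(LM-PCR + sequencing) who want a statistically controlled, segment-level
comparison of two vectors' integration behaviour.

## Method

Integration positions of each vector on one analysis unit — one
(chromosome arm, strand) pair — are modelled as an i.i.d. sample
x₁…xₙ from an unknown density *f* on the unit. The pipeline:

1. **Blind regions.** Restriction digestion (MseI/TTAA by default) plus
   size selection makes positions undetectable when the distance to the
   flanking restriction site falls outside [20, 500) bp. These *blind
   regions* (10–40% of a chromosome) are computed from the genome
   sequence, excised, and the detectable segments concatenated into a
   collapsed coordinate; results are later expanded back.
2. **Density and bands.** On the collapsed axis each vector's density is
   estimated with a Gaussian-kernel estimator
   f̂(x) = (nh)⁻¹ Σᵢ K((x−xᵢ)/h), the bandwidth chosen per vector by
   unbiased (least-squares leave-one-out) cross-validation. Around √f̂ a
   pointwise *variability band* of constant half width
   w = z₍₁₊α₎/₂ · √(R(K)/(4nh)), R(K) = 1/(2√π), is built and
   back-transformed (lower edge clipped at 0); α = 0.99 by default. The
   band reflects estimator variance, not bias — it is not a confidence
   band.
3. **Candidates.** Maximal segments where the two bands are disjoint
   (one lower edge above the other upper edge) are candidate comparative
   hotspots; the vector on top is the winner. Robustness is probed by
   rescaling both bandwidths with a common factor s ∈ [0.05, 20].
4. **Confirmation.** Each candidate is reduced to a 2×2 table of
   inside/outside counts (outside = the vector's genome-wide total minus
   inside), the odds ratio oriented to be ≥ 1, the null OR = 1 tested by
   Fisher's exact test, and all candidates of a run corrected jointly by
   Bonferroni–Holm (significant at adjusted p ≤ 0.05).
5. **Annotation.** Confirmed hotspots are characterised against gene
   intervals (strand-agnostic overlap counts and per-bp density),
   expression present/absent flags (per-hotspot Fisher enrichment vs the
   outside-all-hotspots background), and chromatin read tracks
   (per-group Welch or Mann–Whitney statistics with permutation
   p-values, Holm across tracks).

## Worked example

Everything below is synthetic and seeded; no external data is needed.

```python
from comphot import (AnalysisUnit, blind_map_from_sequence, bands_for_unit,
                     find_candidates, to_genomic, confirm, tests_to_frame)
from comphot.simulate import (Bump, ScenarioSpec, simulate_motif_genome,
                              simulate_sites)

L = 10_000_000
seq = simulate_motif_genome(L, mean_gap=350, seed=1)
unit = AnalysisUnit("chr1", "p", "+", 0, L)
bmap = blind_map_from_sequence(seq, unit)
print(f"blind fraction: {bmap.blind_fraction():.3f}")

spec = ScenarioSpec(unit_length=L, n_sites={"HIV": 1500, "MLV": 1500},
                    bumps=(Bump(3_000_000, 200_000, "HIV", 8.0),),
                    strands=("+",), seed=1)
sets, genomic, truth = simulate_sites(spec, bmap, seed=1)
band_hiv, band_mlv, h_opt = bands_for_unit(sets["HIV"], sets["MLV"])
print(f"h_opt: HIV {h_opt['HIV']:.0f} bp, MLV {h_opt['MLV']:.0f} bp")
cands = to_genomic(find_candidates(band_hiv, band_mlv,
                                   labels=("HIV", "MLV"), unit=unit), bmap)
tests = confirm(cands, genomic)
print(tests_to_frame(tests)[["virus", "start", "end", "length", "OR", "p_adj"]]
      .to_string(index=False))
```

prints

```
blind fraction: 0.291
h_opt: HIV 32182 bp, MLV 189607 bp
virus   start     end  length       OR        p_adj
  HIV 2815890 3183827  367937 5.678641 1.823701e-42
```

Read: ~29% of this simulated arm is blind to the protocol; cross-validation
picks a sharp bandwidth for the bumped HIV sample and a wide one for the
flat MLV sample; exactly one comparative hotspot is found, overlapping the
planted 200 kb bump at 2.9–3.1 Mb, with HIV integration odds ≈ 5.7× MLV
inside it, decisively significant after Holm correction.

The same analysis is available from the shell:

```sh
comphot simulate -o fixtures/            # default synthetic scenario
comphot run --fasta fixtures/genome.fa --arms fixtures/arms.bed \
            --sites fixtures/sites.bed -o out/
```

which writes `blind.bed`, `candidates.tsv`, `hotspots.tsv` and a JSON
summary, all with provenance headers.

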