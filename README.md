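# sohscan

Genetic-diversity metrics from a **single reference genome**, built for
the fragmented short-read assemblies typical of large comparative
sequencing projects — and the cross-species statistics that connect
those metrics to extinction risk.

Conservation genomics often has exactly one sequenced individual per
species. Two quantities can still be read off that one genome:

* **Overall heterozygosity** — high-confidence heterozygous calls per
  callable bp.
* **SoH (segments of homozygosity)** — the genome fraction in extended
  runs without variation. Classic ROH callers need scaffolds longer
  than the runs; on drafts with scaffold N50 of tens of kb they are
  blind. SoH instead cuts scaffolds into 20–50 kb windows, computes the
  per-window heterozygosity rate h_w, and fits a two-component mixture

  &nbsp;&nbsp;&nbsp;&nbsp;w·f₁(h) + (1−w)·f₂(h),&nbsp;&nbsp;h ≥ 0,

  where f₂ is a free normal and f₁ is a normal **truncated at zero**
  (renormalized by 1/(1−Φ(−μ₁/σ₁)), since a rate cannot be negative).
  SoH is the summed length of windows assigned to the low component by
  posterior maximum likelihood, over the total windowed length.

The package also includes the standard genotype QC rules for such
callsets (het-only, GQ > 20, 6 < DP < 100; callable = GQ > 15;
scaffolds within 0.5–2× mean depth and > 10 kb), panel-level analyses
(IUCN ordinal regression, wild/captive t-test, Bonferroni phenotype
screen), a Poisson model of chance-invariant alignment columns
(G·e^(−L)), and simulators for diploid variant landscapes and species
panels with known ground truth. See `docs/methods.md` for the model
details and assumptions.

## Worked example

```python
import sohscan
from sohscan.simulate import GenomeSimConfig, simulate_genome_profile

# a ~30 Mb fragmented draft with 40% of the genome in megabase ROH
config = GenomeSimConfig(f_roh=0.4, theta_in=0.0, mean_roh_len=1_000_000, seed=11)
genome = simulate_genome_profile(config)

scaffolds = sohscan.filter_scaffolds_by_depth(genome.scaffolds)
hc = sohscan.filter_high_confidence(genome.records)
result, mixture, windows = sohscan.estimate_soh(
    scaffolds, hc.records, mask=genome.mask, seed=0
)
print(f"estimated SoH {100*result.soh:.1f}%  "
      f"(true {100*genome.truth.realized_f_roh:.1f}%)")
```

prints

```
estimated SoH 39.7%  (true 41.0%)
```

— the low-heterozygosity mixture component recovers the simulated ROH
fraction to within the window-boundary resolution of the method. The
same pipeline on a default (least-concern-like) genome gives overall
heterozygosity ≈ 0.0022 and SoH ≈ 16%, and the constraint-power model
says a 240-species alignment with total branch length 16.6
substitutions/site leaves only

```
>>> sohscan.expected_invariant_sites(3.1e9, 16.6)
191.5...   # of 3.1 billion positions, ~0.000006%
```

invariant by chance. The scripts in `examples/` walk through each
capability (`python examples/03_soh_estimation.py` produced the numbers
above).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
sohscan simulate genome --out sim/ --seed 1
sohscan filter-variants sim/variants.vcf --scaffolds sim/scaffolds.tsv --out hc.vcf
sohscan soh --vcf hc.vcf --mask sim/callable.bed --scaffolds sim/scaffolds.tsv
sohscan power --genome-size 3.1e9 --branch-length 16.6
sohscan panel --in panel.tsv --out report/
```

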