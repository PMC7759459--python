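"""Synthetic diploid-genome variant landscapes and species panels.

The genome simulator emulates the variant callset of one diploid
individual sequenced at ~40x and assembled into a fragmented draft
(scaffold N50 on the order of tens of kb): heterozygous sites arrive as
a Poisson process whose rate drops inside runs of homozygosity (ROH),
laid down by an alternating exponential segment process. The panel
simulator draws a multi-species table in which diversity degrades with
IUCN extinction-risk rank, with a contaminated subset exercising the
downstream QC exclusions. Both are fully reproducible from a single
integer seed and report their ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sohscan.errors import ConfigError
from sohscan.vcfio import CallableMask, VariantRecord, merge_intervals

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")

_GQ_PASS_BANDS = (30, 40, 50, 99)
_GQ_FAIL_BANDS = (0, 10)
_BASES = ("A", "C", "G", "T")

# gVCF-style quality failure is simulated block-wise: the genome is tiled
# and whole tiles fail together, mimicking locally bad mapping.
FAIL_TILE = 1_000


@dataclass
class GenomeSimConfig:
    """Parameters of the diploid-genome simulator.

    Defaults emulate a least-concern mammal on a DISCOVAR-style draft:
    background heterozygosity 2.6e-3/bp, 17% of the genome in ROH,
    per-site depth ~Poisson(40), scaffold lengths log-normal with N50
    near 60 kb.

    theta_in is the residual within-ROH heterozygosity rate; default 5%
    of theta_out. mean_non_roh_len defaults to the value that makes the
    stationary ROH fraction of the alternating exponential process equal
    f_roh, i.e. mean_roh_len * (1 - f_roh) / f_roh.
    """

    n_scaffolds: int = 600
    scaffold_len_mean: float = 55_000.0
    scaffold_len_sd: float = 45_000.0
    theta_out: float = 2.6e-3
    theta_in: float | None = None          # default: 0.05 * theta_out
    f_roh: float = 0.171
    mean_roh_len: float = 500_000.0
    mean_non_roh_len: float | None = None  # default: derived from f_roh
    mean_depth: float = 40.0
    depth_cv: float = 0.1                  # scaffold-level depth spread
    ab_bias: float = 0.5
    gq_fail_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_in is None:
            self.theta_in = 0.05 * self.theta_out
        if self.n_scaffolds < 1:
            raise ConfigError("n_scaffolds must be >= 1")
        if self.scaffold_len_mean <= 0 or self.scaffold_len_sd < 0:
            raise ConfigError("scaffold_len_mean must be > 0, scaffold_len_sd >= 0")
        if self.theta_out < 0 or self.theta_in < 0:
            raise ConfigError("theta_out and theta_in must be >= 0")
        if self.theta_in > self.theta_out:
            raise ConfigError("theta_in must be <= theta_out")
        if not (0.0 <= self.f_roh <= 1.0):
            raise ConfigError("f_roh must lie in [0, 1]")
        if self.mean_roh_len <= 0:
            raise ConfigError("mean_roh_len must be > 0")
        if self.mean_non_roh_len is None and 0.0 < self.f_roh < 1.0:
            self.mean_non_roh_len = self.mean_roh_len * (1.0 - self.f_roh) / self.f_roh
        if self.mean_non_roh_len is not None and self.mean_non_roh_len <= 0:
            raise ConfigError("mean_non_roh_len must be > 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not (0.0 < self.ab_bias < 1.0):
            raise ConfigError("ab_bias must lie in (0, 1)")
        if not (0.0 <= self.gq_fail_rate < 1.0):
            raise ConfigError("gq_fail_rate must lie in [0, 1)")


@dataclass
class TrueState:
    """Ground truth of one simulated genome."""

    roh_intervals: dict[str, np.ndarray]
    true_het_positions: dict[str, np.ndarray]
    realized_f_roh: float

    def roh_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.roh_intervals.values())
        )


@dataclass
class SimulatedGenome:
    """Bundle returned by :func:`simulate_genome_profile`."""

    scaffolds: pd.DataFrame
    records: list[VariantRecord]
    mask: CallableMask
    truth: TrueState
    config: GenomeSimConfig


def _scaffold_lengths(cfg: GenomeSimConfig, rng: np.random.Generator) -> np.ndarray:
    # log-normal with the requested arithmetic mean/sd
    cv2 = (cfg.scaffold_len_sd / cfg.scaffold_len_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(cfg.scaffold_len_mean) - sigma2 / 2
    lengths = rng.lognormal(mu, np.sqrt(sigma2), cfg.n_scaffolds)
    return np.maximum(lengths.astype(np.int64), 1_000)


def _roh_intervals_for_scaffold(
    length: int, cfg: GenomeSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Alternating ROH / non-ROH segments with exponential lengths."""
    if cfg.f_roh == 0.0:
        return np.empty((0, 2), dtype=np.int64)
    if cfg.f_roh == 1.0:
        return np.array([[0, length]], dtype=np.int64)
    means = {True: cfg.mean_roh_len, False: cfg.mean_non_roh_len}
    in_roh = bool(rng.random() < cfg.f_roh)  # stationary start state
    pos = 0
    out = []
    while pos < length:
        seg = max(1, int(rng.exponential(means[in_roh])))
        end = min(pos + seg, length)
        if in_roh:
            out.append([pos, end])
        pos = end
        in_roh = not in_roh
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _poisson_positions(
    intervals: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Distinct integer positions of a Poisson process over intervals."""
    if rate <= 0 or len(intervals) == 0:
        return np.empty(0, dtype=np.int64)
    out = []
    for s, e in intervals:
        n = rng.poisson(rate * (e - s))
        if n:
            out.append(rng.integers(s, e, size=n))
    if not out:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(out))


def _complement(intervals: np.ndarray, length: int) -> np.ndarray:
    """Complement of merged intervals within [0, length)."""
    out = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append([prev, s])
        prev = max(prev, e)
    if prev < length:
        out.append([prev, length])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def simulate_genome_profile(config: GenomeSimConfig) -> SimulatedGenome:
    """Simulate one diploid genome's scaffold table, heterozygous-site
    callset, callable mask and ground truth.

    Heterozygous sites form a Poisson process at rate theta_out outside
    ROH and theta_in inside. Each site draws DP ~ Poisson(scaffold
    depth), alternate-allele reads ~ Binomial(DP, ab_bias) and a banded
    GQ: a high band (30/40/50/99) in callable tiles, a failing band
    (0/10) inside the gq_fail_rate fraction of tiles that are dropped
    from the callable mask.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lengths = _scaffold_lengths(cfg, rng)
    names = [f"scaffold_{i:05d}" for i in range(cfg.n_scaffolds)]
    depths = np.maximum(
        rng.normal(cfg.mean_depth, cfg.depth_cv * cfg.mean_depth, cfg.n_scaffolds),
        1.0,
    )
    scaffolds = pd.DataFrame(
        {"scaffold": names, "length": lengths, "mean_depth": np.round(depths, 2)}
    )

    roh: dict[str, np.ndarray] = {}
    het_pos: dict[str, np.ndarray] = {}
    mask_ivs: dict[str, np.ndarray] = {}
    records: list[VariantRecord] = []
    total_roh = 0

    for name, length, depth in zip(names, lengths, depths):
        length = int(length)
        iv = _roh_intervals_for_scaffold(length, cfg, rng)
        iv = merge_intervals(iv)
        roh[name] = iv
        total_roh += int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0

        inside = _poisson_positions(iv, cfg.theta_in, rng)
        outside = _poisson_positions(_complement(iv, length), cfg.theta_out, rng)
        pos = np.sort(np.concatenate([inside, outside]))
        het_pos[name] = pos

        # tile-wise GQ failure; callable mask = complement of failed tiles
        n_tiles = -(-length // FAIL_TILE)
        failed = rng.random(n_tiles) < cfg.gq_fail_rate
        if failed.any():
            tidx = np.flatnonzero(failed)
            fail_iv = np.column_stack(
                [tidx * FAIL_TILE, np.minimum((tidx + 1) * FAIL_TILE, length)]
            )
            callable_iv = _complement(merge_intervals(fail_iv), length)
        else:
            callable_iv = np.array([[0, length]], dtype=np.int64)
        mask_ivs[name] = callable_iv

        if len(pos) == 0:
            continue
        in_fail = failed[pos // FAIL_TILE]
        dp = np.maximum(rng.poisson(depth, len(pos)), 1)
        alt_reads = rng.binomial(dp, cfg.ab_bias)
        gq = np.where(
            in_fail,
            rng.choice(_GQ_FAIL_BANDS, len(pos)),
            rng.choice(_GQ_PASS_BANDS, len(pos)),
        )
        ref_alleles = rng.choice(_BASES, len(pos))
        alt_shift = rng.integers(1, 4, len(pos))
        for j, p in enumerate(pos):
            ref = ref_alleles[j]
            alt = _BASES[(_BASES.index(ref) + alt_shift[j]) % 4]
            records.append(
                VariantRecord(
                    scaffold=name, pos=int(p) + 1, ref=ref, alt=alt,
                    genotype="het", gq=int(gq[j]), dp=int(dp[j]),
                    ad=(int(dp[j] - alt_reads[j]), int(alt_reads[j])),
                )
            )

    truth = TrueState(
        roh_intervals=roh,
        true_het_positions=het_pos,
        realized_f_roh=total_roh / int(lengths.sum()),
    )
    return SimulatedGenome(
        scaffolds=scaffolds, records=records,
        mask=CallableMask(mask_ivs), truth=truth, config=cfg,
    )


def refragment(
    genome: SimulatedGenome, parts: int = 2
) -> tuple[pd.DataFrame, list[VariantRecord], CallableMask]:
    """Re-scaffold a simulated genome by cutting every scaffold into
    `parts` equal pieces, remapping records and mask coordinates.

    Models re-assembling the same underlying diploid genome at a
    different fragmentation; the variant landscape itself is unchanged.
    """
    rows = []
    rec_out: list[VariantRecord] = []
    mask_out: dict[str, np.ndarray] = {}
    cuts: dict[str, np.ndarray] = {}
    depth = dict(zip(genome.scaffolds["scaffold"], genome.scaffolds["mean_depth"]))
    for scaf, length in zip(genome.scaffolds["scaffold"], genome.scaffolds["length"]):
        length = int(length)
        bounds = np.linspace(0, length, parts + 1).astype(np.int64)
        cuts[scaf] = bounds
        for i in range(parts):
            s, e = int(bounds[i]), int(bounds[i + 1])
            if e <= s:
                continue
            sub = f"{scaf}.{i}"
            rows.append((sub, e - s, depth[scaf]))
            iv = genome.mask.intervals(scaf)
            lo = np.maximum(iv[:, 0], s)
            hi = np.minimum(iv[:, 1], e)
            keep = hi > lo
            if keep.any():
                mask_out[sub] = np.column_stack([lo[keep] - s, hi[keep] - s])
    for r in genome.records:
        bounds = cuts[r.scaffold]
        i = int(np.searchsorted(bounds, r.pos - 1, side="right") - 1)
        offset = int(bounds[i])
        rec_out.append(
            VariantRecord(
                scaffold=f"{r.scaffold}.{i}", pos=r.pos - offset,
                ref=r.ref, alt=r.alt, genotype=r.genotype,
                gq=r.gq, dp=r.dp, ad=r.ad,
            )
        )
    scaffolds = pd.DataFrame(rows, columns=["scaffold", "length", "mean_depth"])
    return scaffolds, rec_out, CallableMask(mask_out)


def write_genome_profile(genome: SimulatedGenome, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, callable BED, scaffold TSV and truth JSON to a directory."""
    from sohscan.vcfio import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "mask": out / "callable.bed",
        "scaffolds": out / "scaffolds.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(genome.records, genome.scaffolds, paths["vcf"])
    genome.mask.to_bed(paths["mask"])
    genome.scaffolds.to_csv(paths["scaffolds"], sep="\t", index=False)
    truth = {
        "realized_f_roh": genome.truth.realized_f_roh,
        "roh_intervals": {
            k: v.tolist() for k, v in genome.truth.roh_intervals.items() if len(v)
        },
        "n_true_het": int(sum(len(v) for v in genome.truth.true_het_positions.values())),
        "config": {k: v for k, v in asdict(genome.config).items()},
    }
    paths["truth"].write_text(json.dumps(truth))
    return paths


# ---------------------------------------------------------------------------
# Species panel
# ---------------------------------------------------------------------------

# PanTHERIA-style species-level trait names for the phenotype screen.
PHENOTYPE_NAMES = (
    "adult_body_mass_g", "adult_head_body_len_mm", "age_first_birth_d",
    "basal_metabolic_rate", "diet_breadth", "dispersal_age_d",
    "gestation_len_d", "habitat_breadth", "home_range_km2",
    "interbirth_interval_d", "litter_size", "litters_per_year",
    "max_longevity_m", "neonate_body_mass_g", "population_density_n_km2",
    "sexual_maturity_age_d", "social_group_size", "teat_number",
    "trophic_level", "weaning_age_d", "geographic_range_km2",
)


@dataclass
class PanelSimConfig:
    """Parameters of the species-panel simulator.

    Heterozygosity decays multiplicatively with IUCN rank r (LC=0 ... CR=4):
    H = baseline_het * exp(-beta_het * r + eps); SoH grows additively:
    SoH = baseline_soh + beta_soh * r + eps', clipped to [0, 1]. Category
    counts default to a 105-species panel dominated by least-concern
    species. A `contaminated_fraction` of species draws inflated allelic
    balance (and a few extreme heterozygosity values) so that downstream
    QC exclusions have work to do.
    """

    n_per_category: tuple[int, int, int, int, int] = (75, 4, 12, 9, 5)
    baseline_het: float = 0.0026
    beta_het: float = 0.10
    baseline_soh: float = 0.171
    beta_soh: float = 0.04
    noise_sd_log_het: float = 0.35
    noise_sd_soh: float = 0.10
    captive_fraction: float = 0.5
    contaminated_fraction: float = 0.15
    het_outlier_fraction: float = 0.015
    soh_undefined_fraction: float = 0.07
    phenotype_missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_category) != 5 or any(n < 0 for n in self.n_per_category):
            raise ConfigError("n_per_category must be 5 non-negative counts")
        if self.baseline_het <= 0:
            raise ConfigError("baseline_het must be > 0")
        if self.baseline_soh + 4 * self.beta_soh + 3 * self.noise_sd_soh >= 1:
            raise ConfigError(
                "baseline_soh + 4*beta_soh + 3*noise_sd_soh must stay below 1"
            )
        for name in ("captive_fraction", "contaminated_fraction",
                     "het_outlier_fraction", "soh_undefined_fraction",
                     "phenotype_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")


def simulate_species_panel(config: PanelSimConfig) -> pd.DataFrame:
    """Draw a species panel table.

    Columns: species, iucn, het, soh (NaN where the mixture would be
    degenerate), ab, callable_pct, contig_n50, born, plus 21
    PanTHERIA-style phenotype columns drawn independently of the
    diversity metrics (null phenotypes) with missing values sprinkled.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rank, (cat, n) in enumerate(zip(IUCN_CATEGORIES, cfg.n_per_category)):
        for i in range(n):
            eps = rng.normal(0.0, cfg.noise_sd_log_het)
            het = cfg.baseline_het * np.exp(-cfg.beta_het * rank + eps)
            contaminated = rng.random() < cfg.contaminated_fraction
            if rng.random() < cfg.het_outlier_fraction:
                het = rng.uniform(0.021, 0.05)  # assembly/contamination artifact
            soh = np.clip(
                cfg.baseline_soh + cfg.beta_soh * rank
                + rng.normal(0.0, cfg.noise_sd_soh),
                0.0, 1.0,
            )
            if rng.random() < cfg.soh_undefined_fraction:
                soh = np.nan
            ab = (
                np.clip(rng.normal(0.45, 0.06), 0.0, 1.0) if contaminated
                else np.clip(rng.normal(0.22, 0.07), 0.0, 1.0)
            )
            # callable fraction co-varies negatively with heterozygosity
            callable_pct = float(
                np.clip(
                    92.0 - 2600.0 * (het - cfg.baseline_het) + rng.normal(0.0, 1.8),
                    40.0, 99.5,
                )
            )
            rows.append({
                "species": f"sp_{cat}_{i:03d}",
                "iucn": cat,
                "het": float(het),
                "soh": float(soh) if np.isfinite(soh) else np.nan,
                "ab": float(ab),
                "callable_pct": callable_pct,
                "contig_n50": int(rng.lognormal(np.log(47_000), 0.5)),
                "born": "captive" if rng.random() < cfg.captive_fraction else "wild",
            })
    panel = pd.DataFrame(rows)
    n = len(panel)
    for name in PHENOTYPE_NAMES:
        vals = rng.lognormal(rng.uniform(0, 8), 1.0, n)
        missing = rng.random(n) < cfg.phenotype_missing_rate
        vals[missing] = np.nan
        panel[name] = vals
    return panel
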