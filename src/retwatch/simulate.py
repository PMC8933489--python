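"""Synthetic cohort generator with known ground truth.

Emulates the data a resistance-evolution study collects for one patient:

* a multi-clone tumor (a truncal clone at tissue CCF 1 plus subclones),
* tumor-tissue read counts shaped by purity and allele-specific copy number,
* longitudinal plasma duplex pileups in which each clone's contribution to
  circulating tumor DNA follows a per-clone exponential trajectory
  (negative rates = responding under treatment, positive = outgrowing;
  a piecewise rate switch at a configured progression day lets resistant
  clones emerge on therapy),
* clonal-hematopoiesis (CH) contaminant variants with constant allele
  fraction and longer fragments than tumor-derived ones,
* UMI read families with raw per-base sequencing errors for exercising
  duplex consensus collapsing.

Everything is driven by a single integer seed; the same seed reproduces the
same cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ccf import expected_vaf

__all__ = [
    "CloneSpec",
    "SimConfig",
    "SyntheticTruth",
    "build_truth",
    "sample_tissue",
    "sample_plasma_series",
    "simulate_read_families",
    "simulate_hotspot_profiles",
    "simulate_tracking_patient",
    "simulate_resistance_patient",
    "write_cohort",
]


class SimulationConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class CloneSpec:
    """One tumor cell population and its plasma shedding dynamics.

    ``plasma_af0`` is the initial plasma allele fraction of this clone's
    variants (tumor fragments are diploid, so a clone contributing a cfDNA
    fraction f yields variant AF ~ f/2; callers specify the AF directly).
    ``growth_rate`` is the per-day exponential rate of the plasma AF;
    negative means the clone responds to treatment. If ``switch_day`` is
    set, ``growth_rate_post`` applies from that day on (emergent resistant
    clones: near-zero AF with a strongly positive post-switch rate).
    """

    clone_id: str
    tissue_ccf: float
    variants: tuple[str, ...]
    plasma_af0: float
    growth_rate: float
    growth_rate_post: Optional[float] = None
    switch_day: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_ccf <= 1.0:
            raise SimulationConfigError(f"tissue_ccf must be in [0,1], got {self.tissue_ccf}")
        if not 0.0 <= self.plasma_af0 <= 1.0:
            raise SimulationConfigError(f"plasma_af0 must be in [0,1], got {self.plasma_af0}")

    def expected_af(self, day: float) -> float:
        """Expected plasma allele fraction at ``day`` (exponential, clipped to [0,1])."""
        if self.switch_day is None or day <= self.switch_day:
            af = self.plasma_af0 * np.exp(self.growth_rate * day)
        else:
            rate_post = self.growth_rate_post if self.growth_rate_post is not None else self.growth_rate
            af = (
                self.plasma_af0
                * np.exp(self.growth_rate * self.switch_day)
                * np.exp(rate_post * (day - self.switch_day))
            )
        return float(np.clip(af, 0.0, 1.0))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic patient.

    Defaults emulate a targeted-panel study of RET-driven tumors: moderate
    purity (0.6), ~500x tissue coverage, ~1200x unique duplex plasma
    coverage, baseline ctDNA variant AFs of a few percent decaying on
    treatment, and cfDNA fragment lengths of ~145 bp (tumor-derived) vs
    ~167 bp (white-blood-cell / CH derived).
    """

    seed: int
    n_clones: int = 3
    variants_per_clone: int = 5
    purity: float = 0.6
    tcn: int = 2
    lcn: int = 1
    multiplicity: int = 1
    tissue_depth_mean: float = 500.0
    plasma_depth_mean: float = 1200.0
    error_rate: float = 1e-3
    ch_variants: int = 2
    ch_af: float = 0.005
    frag_tumor_mean: float = 145.0
    frag_tumor_sd: float = 20.0
    frag_wbc_mean: float = 167.0
    frag_wbc_sd: float = 20.0
    frag_min: float = 50.0
    frag_max: float = 400.0
    sampling_days: tuple[float, ...] = (0.0, 28.0, 56.0, 84.0)
    progression_day: Optional[float] = None
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    noise_free: bool = False
    clones: Optional[tuple[CloneSpec, ...]] = None

    def __post_init__(self) -> None:
        for name in ("purity",):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise SimulationConfigError(f"{name} must be in (0,1], got {v}")
        for name in ("tissue_depth_mean", "plasma_depth_mean", "error_rate",
                     "ch_af", "overdispersion"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if self.n_clones < 0 or self.variants_per_clone < 0 or self.ch_variants < 0:
            raise SimulationConfigError("counts must be >= 0")
        if self.multiplicity > self.tcn:
            raise SimulationConfigError("multiplicity cannot exceed tcn")


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic patient."""

    clones: tuple[CloneSpec, ...]
    variant_clone: dict[str, str]  # variant_id -> clone_id
    ch_variant_ids: tuple[str, ...]
    ch_af: float
    config: SimConfig

    @property
    def tumor_variant_ids(self) -> list[str]:
        return list(self.variant_clone)

    def clone(self, clone_id: str) -> CloneSpec:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    def expected_af(self, variant_id: str, day: float) -> float:
        """Expected plasma allele fraction of a variant at ``day``."""
        if variant_id in self.ch_variant_ids:
            return self.ch_af  # CH burden is treatment-independent
        return self.clone(self.variant_clone[variant_id]).expected_af(day)

    def is_ch(self, variant_id: str) -> bool:
        return variant_id in self.ch_variant_ids

    def to_dict(self) -> dict:
        return {
            "clones": [dataclasses.asdict(c) for c in self.clones],
            "variant_clone": self.variant_clone,
            "ch_variant_ids": list(self.ch_variant_ids),
            "ch_af": self.ch_af,
        }


# deterministic fake genome coordinates for emitted tables
_GENES = ("RET", "TP53", "KRAS", "PIK3CA", "CDKN2A", "BRAF", "NRAS", "MET", "FGFR1", "PTEN")


def _default_clones(config: SimConfig, rng: np.random.Generator) -> tuple[CloneSpec, ...]:
    """Default clonal architecture: a responding truncal clone plus subclones.

    The truncal clone (tissue CCF 1) sheds at a few percent AF and responds
    (rate -0.05/day). Subclones take decreasing tissue CCFs and smaller
    shedding fractions; if a progression day is configured, subclones after
    the first emerge there with a positive growth rate.
    """
    clones = []
    for i in range(config.n_clones):
        vids = tuple(f"c{i + 1}_v{j}" for j in range(config.variants_per_clone))
        if i == 0:
            clones.append(
                CloneSpec(
                    clone_id="clone_1",
                    tissue_ccf=1.0,
                    variants=vids,
                    plasma_af0=0.04,
                    growth_rate=-0.05,
                )
            )
        else:
            ccf = float(rng.uniform(0.2, 0.8))
            if config.progression_day is not None:
                # emergent resistant clone: undetectable at baseline, grows post-switch
                clones.append(
                    CloneSpec(
                        clone_id=f"clone_{i + 1}",
                        tissue_ccf=ccf,
                        variants=vids,
                        plasma_af0=1e-5,
                        growth_rate=0.0,
                        growth_rate_post=0.08,
                        switch_day=config.progression_day + 10.0 * (i - 1),
                    )
                )
            else:
                clones.append(
                    CloneSpec(
                        clone_id=f"clone_{i + 1}",
                        tissue_ccf=ccf,
                        variants=vids,
                        plasma_af0=float(rng.uniform(0.005, 0.02)),
                        growth_rate=float(rng.uniform(-0.06, -0.02)),
                    )
                )
    return tuple(clones)


def build_truth(config: SimConfig) -> SyntheticTruth:
    """Construct the ground-truth clonal architecture for one patient.

    Deterministic given ``config.seed``. Every variant belongs to exactly one
    clone or to the CH compartment.
    """
    rng = np.random.default_rng(config.seed)
    clones = config.clones if config.clones is not None else _default_clones(config, rng)
    total_af0 = sum(c.plasma_af0 for c in clones)
    if total_af0 > 1.0:
        raise SimulationConfigError(
            f"summed initial plasma allele fractions exceed 1 ({total_af0:.3f})"
        )
    variant_clone: dict[str, str] = {}
    for c in clones:
        for v in c.variants:
            if v in variant_clone:
                raise SimulationConfigError(f"variant {v} assigned to multiple clones")
            variant_clone[v] = c.clone_id
    ch_ids = tuple(f"ch_{k}" for k in range(config.ch_variants))
    return SyntheticTruth(
        clones=tuple(clones),
        variant_clone=variant_clone,
        ch_variant_ids=ch_ids,
        ch_af=config.ch_af,
        config=config,
    )


def _draw_alt(rng: np.random.Generator, depth: np.ndarray, p: np.ndarray,
              rho: float, noise_free: bool) -> np.ndarray:
    """Alt counts given depth: binomial, beta-binomial (rho > 0), or exact mean."""
    p = np.clip(p, 0.0, 1.0)
    if noise_free:
        return np.rint(depth * p).astype(int)
    if rho > 0:
        # beta-binomial with correlation rho: a+b = (1-rho)/rho
        s = (1.0 - rho) / rho
        a = np.maximum(p * s, 1e-9)
        b = np.maximum((1.0 - p) * s, 1e-9)
        return rng.binomial(depth, rng.beta(a, b))
    return rng.binomial(depth, p)


def sample_tissue(truth: SyntheticTruth, config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Draw tumor-tissue read counts for every tumor variant.

    Depth is Poisson around ``tissue_depth_mean``; alt counts are binomial at
    the expected VAF implied by the clone's tissue CCF, the purity and the
    per-variant copy state. Returns a MAF-like table with columns
    chrom, pos, ref, alt, gene, protein_change, t_alt_count, t_depth plus
    variant_id, tcn, lcn and the true CCF.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    i = 0
    for clone in truth.clones:
        for vid in clone.variants:
            vaf = expected_vaf(clone.tissue_ccf, config.purity, config.tcn, config.multiplicity) \
                if clone.tissue_ccf > 0 else 0.0
            depth = int(rng.poisson(config.tissue_depth_mean)) if not config.noise_free \
                else int(round(config.tissue_depth_mean))
            alt = int(_draw_alt(rng, np.array([depth]), np.array([vaf]),
                                config.overdispersion, config.noise_free)[0])
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": str(1 + i % 22),
                    "pos": 1_000_000 + 1000 * i,
                    "ref": "A",
                    "alt": "T",
                    "gene": _GENES[i % len(_GENES)],
                    "protein_change": f"p.X{100 + i}Y",
                    "t_alt_count": alt,
                    "t_depth": depth,
                    "tcn": config.tcn,
                    "lcn": config.lcn,
                    "true_ccf": clone.tissue_ccf,
                    "clone_id": clone.clone_id,
                }
            )
            i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "ref", "alt", "gene", "protein_change",
            "t_alt_count", "t_depth", "tcn", "lcn", "true_ccf", "clone_id",
        ],
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float,
               hi: float, n: int) -> np.ndarray:
    x = rng.normal(mean, sd, size=n)
    bad = (x < lo) | (x > hi)
    while bad.any():  # redraw-outside truncation
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def sample_plasma_series(
    truth: SyntheticTruth, config: Optional[SimConfig] = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Draw the longitudinal plasma duplex pileups and alt-fragment lengths.

    Returns ``(pileup, fragment_lengths)``: the pileup table has one row per
    (day, variant) with duplex_depth, duplex_alt and hotspot_flag (tumor
    variants are flagged as known cancer hotspots; CH contaminants are not);
    ``fragment_lengths`` maps variant_id to the lengths of its alt-supporting
    fragments pooled over days (tumor variants short, CH variants long).
    """
    config = config or truth.config
    if len(config.sampling_days) == 0:
        raise SimulationConfigError("sampling_days must be non-empty")
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    frags: dict[str, list[np.ndarray]] = {}
    all_ids = truth.tumor_variant_ids + list(truth.ch_variant_ids)
    for day in config.sampling_days:
        for vid in all_ids:
            af = truth.expected_af(vid, day)
            # duplex residual error: a raw error survives consensus only when
            # both strands flip identically, so it enters quadratically
            p = min(1.0, af + config.error_rate**2)
            depth = int(rng.poisson(config.plasma_depth_mean)) if not config.noise_free \
                else int(round(config.plasma_depth_mean))
            alt = int(_draw_alt(rng, np.array([depth]), np.array([p]),
                                config.overdispersion, config.noise_free)[0])
            rows.append(
                {
                    "day": day,
                    "variant_id": vid,
                    "duplex_depth": depth,
                    "duplex_alt": alt,
                    "hotspot_flag": not truth.is_ch(vid),
                    "true_af": af,
                    "is_ch": truth.is_ch(vid),
                }
            )
            if alt > 0:
                if truth.is_ch(vid):
                    ln = _truncnorm(rng, config.frag_wbc_mean, config.frag_wbc_sd,
                                    config.frag_min, config.frag_max, alt)
                else:
                    ln = _truncnorm(rng, config.frag_tumor_mean, config.frag_tumor_sd,
                                    config.frag_min, config.frag_max, alt)
                frags.setdefault(vid, []).append(ln)
    pileup = pd.DataFrame(
        rows,
        columns=["day", "variant_id", "duplex_depth", "duplex_alt",
                 "hotspot_flag", "true_af", "is_ch"],
    )
    fragment_lengths = {vid: np.concatenate(chunks) for vid, chunks in frags.items()}
    return pileup, fragment_lengths


def simulate_read_families(
    af: float,
    n_families: int,
    reads_per_strand_mean: float,
    error_rate: float,
    seed: int,
    ref_base: str = "A",
    alt_base: str = "T",
) -> pd.DataFrame:
    """Simulate UMI read families at one position for duplex-consensus testing.

    Each family is one original cfDNA duplex: its true base is the alt allele
    with probability ``af``; top- and bottom-strand read counts are drawn
    independently (Poisson around ``reads_per_strand_mean``); every raw read's
    base flips to the other allele with probability ``error_rate``.

    Returns the read-family table (one row per raw read) with columns
    family_id, umi_pair, frag_start, frag_end, strand, base, fragment_length.
    """
    if n_families < 0 or reads_per_strand_mean < 0:
        raise ValueError("counts must be >= 0")
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"af must be in [0,1], got {af}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    rows = []
    for fam in range(n_families):
        true_alt = rng.random() < af
        true_base = alt_base if true_alt else ref_base
        umi_a, umi_b = ("".join(rng.choice(alphabet, 3)) for _ in range(2))
        umi_pair = "+".join(sorted((umi_a, umi_b)))
        start = int(rng.integers(1_000_000, 1_000_500))
        length = int(rng.integers(120, 180))
        end = start + length - 1
        for strand in ("top", "bottom"):
            n_reads = int(rng.poisson(reads_per_strand_mean))
            for _ in range(n_reads):
                base = true_base
                if error_rate > 0 and rng.random() < error_rate:
                    base = ref_base if base == alt_base else alt_base
                rows.append(
                    {
                        "family_id": f"fam{fam}",
                        "umi_pair": umi_pair,
                        "frag_start": start,
                        "frag_end": end,
                        "strand": strand,
                        "base": base,
                        "fragment_length": length,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["family_id", "umi_pair", "frag_start", "frag_end",
                 "strand", "base", "fragment_length"],
    )


def simulate_hotspot_profiles(
    seed: int,
    n_null: int = 200,
    n_planted: int = 20,
    protein_length: int = 500,
    n_mutations: int = 50,
    hotspot_k: int = 20,
):
    """Null-plus-planted gene cohort for hotspot-caller calibration.

    ``n_null`` genes receive ``n_mutations`` substitutions scattered
    uniformly over ``protein_length`` residues (no true hotspot);
    ``n_planted`` genes receive ``hotspot_k`` recurrent mutations at one
    random residue plus ``n_mutations - hotspot_k`` scattered ones.

    Returns ``(profiles, null_genes, planted_sites)`` where ``null_genes``
    is the set of gene names without a planted hotspot and ``planted_sites``
    maps planted gene -> hotspot residue.
    """
    from .hotspots import GeneMutationProfile

    rng = np.random.default_rng(seed)
    profiles = []
    null_genes = set()
    planted_sites: dict[str, int] = {}

    def scatter(n: int) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in rng.integers(1, protein_length + 1, size=n):
            counts[int(r)] = counts.get(int(r), 0) + 1
        return counts

    for i in range(n_null):
        gene = f"null_{i}"
        null_genes.add(gene)
        profiles.append(GeneMutationProfile(gene, protein_length, counts=scatter(n_mutations)))
    for i in range(n_planted):
        gene = f"planted_{i}"
        counts = scatter(n_mutations - hotspot_k)
        site = int(rng.integers(1, protein_length + 1))
        counts[site] = counts.get(site, 0) + hotspot_k
        planted_sites[gene] = site
        profiles.append(GeneMutationProfile(gene, protein_length, counts=counts))
    return profiles, null_genes, planted_sites


#: switch days yielding one new detectable clone per follow-up draw under
#: the default 28-day sampling grid and a 0.2/day post-switch growth rate
_EMERGENCE_SWITCH_DAYS = (5.0, 35.0, 63.0, 91.0)


def simulate_tracking_patient(
    seed: int,
    n_clones: int = 3,
    variants_per_clone: int = 5,
    depth: float = 2000.0,
    noise_free: bool = False,
    days: tuple[float, ...] = (0.0, 28.0, 56.0, 84.0, 112.0),
) -> SyntheticTruth:
    """A longitudinal patient for subclone-recovery studies.

    Clone 1 is the responding driver clone (AF 4% falling at -0.05/day);
    each further clone is an emergent resistant population, undetectable at
    baseline, switching to +0.2/day growth at staggered progression days so
    each becomes detectable at a distinct follow-up draw.
    """
    if not 1 <= n_clones <= 1 + len(_EMERGENCE_SWITCH_DAYS):
        raise SimulationConfigError(f"n_clones must be in [1, 5], got {n_clones}")
    clones = [
        CloneSpec(
            "clone_1",
            tissue_ccf=1.0,
            variants=tuple(f"c1_v{j}" for j in range(variants_per_clone)),
            plasma_af0=0.04,
            growth_rate=-0.05,
        )
    ]
    for i in range(1, n_clones):
        clones.append(
            CloneSpec(
                f"clone_{i + 1}",
                tissue_ccf=0.3,
                variants=tuple(f"c{i + 1}_v{j}" for j in range(variants_per_clone)),
                plasma_af0=1e-4,
                growth_rate=0.0,
                growth_rate_post=0.2,
                switch_day=_EMERGENCE_SWITCH_DAYS[i - 1],
            )
        )
    cfg = SimConfig(
        seed=seed,
        clones=tuple(clones),
        ch_variants=0,
        plasma_depth_mean=depth,
        noise_free=noise_free,
        sampling_days=days,
    )
    return build_truth(cfg)


def simulate_resistance_patient(
    seed: int,
    mechanism: str = "on_target",
    depth: float = 2000.0,
    noise_free: bool = False,
    days: tuple[float, ...] = (0.0, 28.0, 56.0, 84.0, 112.0),
) -> tuple[SyntheticTruth, pd.DataFrame]:
    """A patient with a planted resistance mechanism and annotated variants.

    ``mechanism`` is one of ``on_target`` (emergent RET G810C subclone),
    ``bypass`` (emergent KRAS G12V subclone), ``both`` (the two emerging at
    different progression days) or ``none``. Returns the truth plus a variant
    metadata table (variant_id, gene, protein_change) for annotation.
    """
    if mechanism not in {"on_target", "bypass", "both", "none"}:
        raise SimulationConfigError(f"unknown mechanism {mechanism!r}")
    clones = [
        CloneSpec("driver_clone", 1.0, ("RET_fusion", "TP53_R175H"),
                  plasma_af0=0.04, growth_rate=-0.05)
    ]
    meta = [
        {"variant_id": "RET_fusion", "gene": "RET", "protein_change": ""},
        {"variant_id": "TP53_R175H", "gene": "TP53", "protein_change": "R175H"},
    ]
    if mechanism in ("on_target", "both"):
        clones.append(
            CloneSpec("ret_sf_clone", 0.3, ("RET_G810C",), plasma_af0=1e-4,
                      growth_rate=0.0, growth_rate_post=0.2, switch_day=30.0)
        )
        meta.append({"variant_id": "RET_G810C", "gene": "RET", "protein_change": "G810C"})
    if mechanism in ("bypass", "both"):
        clones.append(
            CloneSpec("kras_clone", 0.2, ("KRAS_G12V",), plasma_af0=1e-4,
                      growth_rate=0.0, growth_rate_post=0.2, switch_day=58.0)
        )
        meta.append({"variant_id": "KRAS_G12V", "gene": "KRAS", "protein_change": "G12V"})
    cfg = SimConfig(
        seed=seed,
        clones=tuple(clones),
        ch_variants=0,
        plasma_depth_mean=depth,
        noise_free=noise_free,
        sampling_days=days,
    )
    return build_truth(cfg), pd.DataFrame(meta)


def write_cohort(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write one patient's synthetic data as plain-text tables + truth JSON.

    Emits: variants.maf.tsv (MAF-like), copy_states.tsv, plasma_pileup.tsv,
    read_families.tsv, truth.json. Returns the paths keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    tissue = sample_tissue(truth, config)
    pileup, _ = sample_plasma_series(truth, config)
    families = simulate_read_families(
        af=0.01, n_families=200, reads_per_strand_mean=3,
        error_rate=config.error_rate, seed=config.seed + 3,
    )

    paths = {}
    maf = tissue[["chrom", "pos", "ref", "alt", "gene", "protein_change",
                  "t_alt_count", "t_depth"]].copy()
    maf.insert(0, "variant_id", tissue["variant_id"])
    paths["maf"] = outdir / "variants.maf.tsv"
    maf.to_csv(paths["maf"], sep="\t", index=False)

    cn = tissue[["chrom", "pos"]].copy()
    cn["start"] = cn["pos"] - 500
    cn["end"] = cn["pos"] + 500
    cn["tcn"] = config.tcn
    cn["lcn"] = config.lcn
    paths["copy_states"] = outdir / "copy_states.tsv"
    cn[["chrom", "start", "end", "tcn", "lcn"]].to_csv(paths["copy_states"], sep="\t", index=False)

    paths["plasma_pileup"] = outdir / "plasma_pileup.tsv"
    pileup[["day", "variant_id", "duplex_depth", "duplex_alt", "hotspot_flag"]].to_csv(
        paths["plasma_pileup"], sep="\t", index=False
    )

    paths["read_families"] = outdir / "read_families.tsv"
    families.to_csv(paths["read_families"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return paths
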