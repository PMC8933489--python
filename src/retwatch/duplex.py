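"""Duplex consensus calling, plasma variant filters, fragment sizes, phasing.

Ultra-deep cfDNA sequencing tags both strands of each original DNA duplex
with unique molecular identifiers (UMIs). Reads sharing a (canonicalised UMI
pair, fragment start, fragment end) key form one family; a per-strand
simplex consensus is taken first and a duplex consensus base is emitted only
when both strands exist and agree — which suppresses PCR and sequencing
errors that appear on a single strand.

Variant calling on the duplex pileup applies the assay's filters: at least
one duplex read at a known cancer hotspot or at least three elsewhere, a
0.1% allele-fraction limit of detection, and removal of any variant observed
in the matched buffy-coat (clonal-hematopoiesis) sample. Tumor-derived
cfDNA fragments are shorter than white-blood-cell fragments, which gives an
orthogonal rank-sum check; fusion allele fractions use the flanking depth on
both sides of the breakpoint, and read-backed phasing classifies mutation
pairs as cis or trans from fragments covering both positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlasmaVariantCall",
    "FragmentSizeResult",
    "PhasingResult",
    "canonical_family_key",
    "build_duplex_consensus",
    "call_plasma_variants",
    "fragment_size_test",
    "fusion_af",
    "phase_pair",
    "LOD_AF",
    "MIN_ALT_HOTSPOT",
    "MIN_ALT_NON_HOTSPOT",
]

#: assay limit of detection on the duplex allele fraction
LOD_AF = 0.001
MIN_ALT_HOTSPOT = 1
MIN_ALT_NON_HOTSPOT = 3


@dataclass(frozen=True)
class PlasmaVariantCall:
    variant_id: str
    duplex_depth: int
    duplex_alt: int
    hotspot_flag: bool
    ch_filtered: bool
    passed: bool
    assessable: bool = True

    @property
    def af(self) -> float:
        return self.duplex_alt / self.duplex_depth if self.duplex_depth else float("nan")


@dataclass(frozen=True)
class FragmentSizeResult:
    median_difference: float
    p_value: float
    assessable: bool


@dataclass(frozen=True)
class PhasingResult:
    variant_a: str
    variant_b: str
    both_alt: int
    only_a: int
    only_b: int
    neither: int
    call: str  # cis | trans | ambiguous | not_assessable


def canonical_family_key(umi_pair: str, frag_start: int, frag_end: int) -> str:
    """Canonical family key: lexicographically sorted UMI pair + fragment ends.

    Sorting the UMI tags lets the top- and bottom-strand families of one
    duplex share a key regardless of read orientation.
    """
    tags = sorted(str(umi_pair).split("+"))
    return f"{'+'.join(tags)}:{int(frag_start)}-{int(frag_end)}"


def _simplex_consensus(bases: Sequence[str], min_agreement: float, min_reads: int) -> str:
    if len(bases) < min_reads:
        return "N"
    vals, counts = np.unique(np.asarray(bases, dtype=object), return_counts=True)
    i = int(np.argmax(counts))
    if counts[i] / len(bases) >= min_agreement:
        return str(vals[i])
    return "N"


def build_duplex_consensus(
    reads: pd.DataFrame,
    min_agreement: float = 0.9,
    min_reads_per_strand: int = 1,
) -> pd.DataFrame:
    """Collapse a read-family table into duplex consensus reads.

    ``reads`` has one row per raw read with columns umi_pair, frag_start,
    frag_end, strand (top/bottom), base and optionally fragment_length.
    Per family and strand a simplex consensus base requires ``min_agreement``
    (default 90%) of that strand's reads; the duplex base requires both
    simplex bases present and equal, else N. Families covered on a single
    strand emit nothing.

    Returns one row per duplex family: family_key, base, n_top, n_bottom,
    fragment_length.
    """
    required = {"umi_pair", "frag_start", "frag_end", "strand", "base"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    if len(reads) == 0:
        return pd.DataFrame(
            columns=["family_key", "base", "n_top", "n_bottom", "fragment_length"]
        )
    df = reads.copy()
    bad = ~df["strand"].isin(["top", "bottom"])
    if bad.any():
        raise ValueError(f"unknown strand labels: {sorted(df.loc[bad, 'strand'].unique())}")
    df["family_key"] = [
        canonical_family_key(u, s, e)
        for u, s, e in zip(df["umi_pair"], df["frag_start"], df["frag_end"])
    ]
    out = []
    for key, fam in df.groupby("family_key", sort=True):
        strands = {}
        for strand, sub in fam.groupby("strand"):
            strands[strand] = _simplex_consensus(
                list(sub["base"]), min_agreement, min_reads_per_strand
            )
        if "top" not in strands or "bottom" not in strands:
            continue  # both-strand representation required
        top, bottom = strands["top"], strands["bottom"]
        base = top if (top == bottom and top != "N") else "N"
        frag_len = (
            float(fam["fragment_length"].iloc[0])
            if "fragment_length" in fam.columns
            else float(fam["frag_end"].iloc[0] - fam["frag_start"].iloc[0] + 1)
        )
        out.append(
            {
                "family_key": key,
                "base": base,
                "n_top": int((fam["strand"] == "top").sum()),
                "n_bottom": int((fam["strand"] == "bottom").sum()),
                "fragment_length": frag_len,
            }
        )
    return pd.DataFrame(out, columns=["family_key", "base", "n_top", "n_bottom", "fragment_length"])


def call_plasma_variants(
    pileup: pd.DataFrame,
    hotspot_ids: Optional[Iterable[str]] = None,
    buffy_pileup: Optional[pd.DataFrame] = None,
    lod_af: float = LOD_AF,
    min_alt_hotspot: int = MIN_ALT_HOTSPOT,
    min_alt_non_hotspot: int = MIN_ALT_NON_HOTSPOT,
    buffy_min_alt: int = 1,
) -> list[PlasmaVariantCall]:
    """Apply the plasma calling filters to a duplex pileup.

    ``pileup`` has columns variant_id, duplex_depth, duplex_alt and may carry
    hotspot_flag (else membership in ``hotspot_ids`` is used). A variant
    passes when its duplex AF is at or above the limit of detection (default
    0.1%) and its duplex alt count meets the hotspot-dependent minimum (1 at
    known cancer hotspots, 3 elsewhere), and it is not seen (``buffy_min_alt``
    or more alt duplex reads) in the matched buffy-coat pileup.

    A variant at zero depth is reported as not assessable rather than absent.
    """
    hotspots = set(hotspot_ids) if hotspot_ids is not None else None
    buffy_alt: dict[str, int] = {}
    if buffy_pileup is not None:
        for r in buffy_pileup.itertuples():
            buffy_alt[str(r.variant_id)] = int(r.duplex_alt)
    calls = []
    for r in pileup.itertuples():
        vid = str(r.variant_id)
        depth = int(r.duplex_depth)
        alt = int(r.duplex_alt)
        if hotspots is not None:
            hotspot = vid in hotspots
        else:
            hotspot = bool(getattr(r, "hotspot_flag", False))
        if depth < 1:
            calls.append(
                PlasmaVariantCall(vid, depth, alt, hotspot, ch_filtered=False,
                                  passed=False, assessable=False)
            )
            continue
        ch = buffy_alt.get(vid, 0) >= buffy_min_alt
        af = alt / depth
        min_alt = min_alt_hotspot if hotspot else min_alt_non_hotspot
        passed = (af >= lod_af) and (alt >= min_alt) and not ch
        calls.append(
            PlasmaVariantCall(vid, depth, alt, hotspot, ch_filtered=ch, passed=passed)
        )
    return calls


def fragment_size_test(
    candidate_lengths: Sequence[float],
    reference_lengths: Sequence[float],
    min_fragments: int = 10,
) -> FragmentSizeResult:
    """One-sided rank-sum test that candidate fragments are shorter than reference.

    Tumor-derived cfDNA fragments run shorter than white-blood-cell-derived
    ones; a small one-sided p-value supports a tumor origin for the candidate
    variant's fragments. Returns the median difference (candidate - reference)
    and the Mann-Whitney one-sided p; fewer than ``min_fragments`` per group
    yields a not-assessable result.
    """
    cand = np.asarray(candidate_lengths, dtype=float)
    ref = np.asarray(reference_lengths, dtype=float)
    if len(cand) < min_fragments or len(ref) < min_fragments:
        return FragmentSizeResult(float("nan"), float("nan"), assessable=False)
    shift = float(np.median(cand) - np.median(ref))
    stat = stats.mannwhitneyu(cand, ref, alternative="less")
    return FragmentSizeResult(shift, float(stat.pvalue), assessable=True)


def fusion_af(spanning_support: int, depth_5prime: int, depth_3prime: int) -> float:
    """Fusion allele fraction from breakpoint-spanning support and flanking depths.

    af = spanning / mean(depth_5prime, depth_3prime), clipped to [0, 1].
    """
    if spanning_support < 0 or depth_5prime < 0 or depth_3prime < 0:
        raise ValueError("counts must be >= 0")
    if depth_5prime + depth_3prime == 0:
        raise ValueError("zero flanking depth on both sides of the breakpoint")
    mean_depth = 0.5 * (depth_5prime + depth_3prime)
    af = spanning_support / mean_depth
    if af > 1.0:
        warnings.warn(
            "spanning support exceeds flanking depth; fusion AF clipped to 1",
            stacklevel=2,
        )
        af = 1.0
    return af


def phase_pair(
    fragments: pd.DataFrame,
    variant_a: str = "A",
    variant_b: str = "B",
    cis_bound: float = 0.8,
    trans_bound: float = 0.2,
    min_informative: int = 3,
) -> PhasingResult:
    """Classify a mutation pair as cis or trans from dual-covering fragments.

    ``fragments`` has one row per duplex fragment covering both positions with
    boolean columns ``alt_a`` and ``alt_b``. Among informative fragments
    (those carrying at least one of the two alt alleles), the pair is *cis*
    when the fraction carrying both alts is >= ``cis_bound`` (default 0.8),
    *trans* when <= ``trans_bound`` (0.2), else ambiguous. Fewer than
    ``min_informative`` informative fragments -> not assessable.
    """
    required = {"alt_a", "alt_b"}
    missing = required - set(fragments.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    a = fragments["alt_a"].astype(bool).to_numpy()
    b = fragments["alt_b"].astype(bool).to_numpy()
    both = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    informative = both + only_a + only_b
    if informative < min_informative:
        call = "not_assessable"
    else:
        frac_both = both / informative
        if frac_both >= cis_bound:
            call = "cis"
        elif frac_both <= trans_bound:
            call = "trans"
        else:
            call = "ambiguous"
    return PhasingResult(variant_a, variant_b, both, only_a, only_b, neither, call)
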