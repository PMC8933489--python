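"""Mutational hotspot detection from cohort mutation tables.

Substitution hotspots are assessed per protein residue with a truncated
binomial model: given a gene with ``n`` substitutions distributed over its
``L`` residues with per-residue mutability weights ``w_i``, the count at
residue i is Binomial(n, p_i) with p_i = w_i / sum(w). The reported p-value
is the upper tail P(X >= k), by default conditioned on the residue being
mutated at all (X >= 1), since only mutated residues are ever tested.

Small in-frame indels are grouped by a maximal-common-region rule (overlap
clusters; the shared core of each cluster) and each region is tested with a
uniform background p = span / L, without a mutability model.

All residue and region tests are pooled into a single family and adjusted
with the Benjamini–Yekutieli step-up procedure; hotspots with adjusted
p < 0.1 are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneMutationProfile",
    "hotspot_pvalue",
    "adjust_by",
    "group_indels_mcr",
    "call_hotspots",
    "HotspotModel",
    "HotspotResults",
    "FDR_THRESHOLD",
]

FDR_THRESHOLD = 0.1


@dataclass
class GeneMutationProfile:
    """Per-residue substitution counts and mutability weights for one gene.

    ``counts`` maps 1-based residue -> number of substitutions observed there;
    ``weights`` maps residue -> relative mutability (uniform when omitted).
    """

    gene: str
    protein_length: int
    counts: dict[int, int] = field(default_factory=dict)
    weights: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError(f"{self.gene}: protein_length must be >= 1")
        for res, k in self.counts.items():
            if not 1 <= res <= self.protein_length:
                raise ValueError(f"{self.gene}: residue {res} outside protein")
            if k < 0:
                raise ValueError("counts must be >= 0")

    @property
    def n_mutations(self) -> int:
        return int(sum(self.counts.values()))

    def residue_probability(self, residue: int) -> float:
        """Background probability p_i that one mutation lands on ``residue``."""
        if self.weights is None:
            return 1.0 / self.protein_length
        total = sum(self.weights.get(r, 0.0) for r in range(1, self.protein_length + 1))
        if total <= 0:
            raise ValueError(f"{self.gene}: mutability weights sum to zero")
        return self.weights.get(residue, 0.0) / total


def hotspot_pvalue(k: int, n: int, p: float, truncated: bool = True) -> float:
    """Upper-tail binomial hotspot p-value, P(X >= k) with X ~ Binom(n, p).

    With ``truncated=True`` (default) and k >= 1 the tail is conditioned on
    the position being mutated at all: P(X >= k) / P(X >= 1). k = 0 always
    returns 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"background probability must be in (0,1), got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    tail = float(stats.binom.sf(k - 1, n, p))
    if truncated:
        p_any = float(stats.binom.sf(0, n, p))
        tail = tail / p_any if p_any > 0 else 1.0
    return min(1.0, max(tail, np.nextafter(0, 1)))


def adjust_by(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (step-up with harmonic inflation)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def group_indels_mcr(indel_intervals: Sequence[tuple[int, int]]) -> list[tuple[tuple[int, int], int]]:
    """Group indel residue spans into maximal-common-region clusters.

    Overlapping intervals (1-based inclusive) are merged single-linkage into
    clusters. Each cluster's region is the intersection of its members when
    non-empty; otherwise (a chain whose ends do not all meet) the region of
    maximal overlap depth. Returns ``[(region, k), ...]`` with k the number
    of indel events in the cluster.
    """
    for s, e in indel_intervals:
        if s > e:
            raise ValueError(f"interval start {s} exceeds end {e}")
    if not indel_intervals:
        return []
    ivals = sorted(indel_intervals)
    clusters: list[list[tuple[int, int]]] = [[ivals[0]]]
    cur_end = ivals[0][1]
    for s, e in ivals[1:]:
        if s <= cur_end:  # shares >= 1 residue with the running cluster
            clusters[-1].append((s, e))
            cur_end = max(cur_end, e)
        else:
            clusters.append([(s, e)])
            cur_end = e
    out = []
    for members in clusters:
        lo = max(s for s, _ in members)
        hi = min(e for _, e in members)
        if lo <= hi:
            region = (lo, hi)
        else:
            # chained overlaps with empty global intersection: take the
            # positions covered by the most members (first maximal run)
            span_lo = min(s for s, _ in members)
            span_hi = max(e for _, e in members)
            depth = np.zeros(span_hi - span_lo + 1, dtype=int)
            for s, e in members:
                depth[s - span_lo : e - span_lo + 1] += 1
            best = depth.max()
            idx = np.nonzero(depth == best)[0]
            run_start = idx[0]
            run_end = run_start
            for j in idx[1:]:
                if j == run_end + 1:
                    run_end = j
                else:
                    break
            region = (int(run_start + span_lo), int(run_end + span_lo))
        out.append((region, len(members)))
    return out


def call_hotspots(
    profiles: Sequence[GeneMutationProfile],
    indels: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    fdr: float = FDR_THRESHOLD,
    truncated: bool = True,
) -> pd.DataFrame:
    """Test every mutated residue (and indel region) and BY-adjust in one family.

    Returns a DataFrame with columns gene, start, end, kind (substitution /
    indel), k, n, p_value, q_value, significant — sorted by q_value.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one gene profile")
    rows = []
    for prof in profiles:
        n = prof.n_mutations
        for residue, k in sorted(prof.counts.items()):
            if k < 1:
                continue
            p_i = prof.residue_probability(residue)
            rows.append(
                {
                    "gene": prof.gene,
                    "start": residue,
                    "end": residue,
                    "kind": "substitution",
                    "k": k,
                    "n": n,
                    "p_value": hotspot_pvalue(k, n, p_i, truncated=truncated),
                }
            )
    if indels:
        lengths = {p.gene: p.protein_length for p in profiles}
        for gene, intervals in indels.items():
            if gene not in lengths:
                raise ValueError(f"indels given for unknown gene {gene}")
            L = lengths[gene]
            n_indel = len(intervals)
            for (lo, hi), k in group_indels_mcr(list(intervals)):
                span_p = (hi - lo + 1) / L
                span_p = min(span_p, 1.0 - 1e-12)
                rows.append(
                    {
                        "gene": gene,
                        "start": lo,
                        "end": hi,
                        "kind": "indel",
                        "k": k,
                        "n": n_indel,
                        "p_value": hotspot_pvalue(k, n_indel, span_p, truncated=truncated),
                    }
                )
    res = pd.DataFrame(
        rows, columns=["gene", "start", "end", "kind", "k", "n", "p_value"]
    )
    if len(res):
        res["q_value"] = adjust_by(res["p_value"].to_numpy())
        res["significant"] = res["q_value"] < fdr
        res = res.sort_values(["q_value", "p_value", "gene", "start"]).reset_index(drop=True)
    else:
        res["q_value"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    return res


class HotspotModel:
    """Hotspot model over a cohort MAF-like mutation table.

    ``data`` needs columns gene, protein_position and variant_class
    (``missense``-like substitutions vs ``inframe_indel`` rows, the latter
    optionally with protein_end for multi-residue spans); ``protein_lengths``
    maps gene -> residue count. Optional per-residue mutability weights come
    as a DataFrame with columns gene, residue, weight.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        protein_lengths: Mapping[str, int],
        weights: Optional[pd.DataFrame] = None,
    ):
        required = {"gene", "protein_position", "variant_class"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        self.data = data.copy()
        self.protein_lengths = dict(protein_lengths)
        self.weights = weights

    def _profiles(self) -> tuple[list[GeneMutationProfile], dict[str, list[tuple[int, int]]]]:
        wmap: dict[str, dict[int, float]] = {}
        if self.weights is not None:
            for r in self.weights.itertuples():
                wmap.setdefault(r.gene, {})[int(r.residue)] = float(r.weight)
        profiles = []
        indels: dict[str, list[tuple[int, int]]] = {}
        for gene, sub in self.data.groupby("gene"):
            if gene not in self.protein_lengths:
                raise ValueError(f"no protein length for gene {gene}")
            counts: dict[int, int] = {}
            for r in sub.itertuples():
                pos = int(r.protein_position)
                if str(r.variant_class).lower().startswith("inframe"):
                    end = int(getattr(r, "protein_end", pos) or pos)
                    indels.setdefault(gene, []).append((pos, end))
                else:
                    counts[pos] = counts.get(pos, 0) + 1
            profiles.append(
                GeneMutationProfile(
                    gene=gene,
                    protein_length=int(self.protein_lengths[gene]),
                    counts=counts,
                    weights=wmap.get(gene),
                )
            )
        return profiles, indels

    def fit(self, fdr: float = FDR_THRESHOLD, truncated: bool = True) -> "HotspotResults":
        profiles, indels = self._profiles()
        table = call_hotspots(profiles, indels or None, fdr=fdr, truncated=truncated)
        return HotspotResults(self, table, fdr=fdr)


class HotspotResults:
    """Hotspot test results with a tabular summary."""

    def __init__(self, model: HotspotModel, table: pd.DataFrame, fdr: float):
        self.model = model
        self.table = table
        self.fdr = fdr

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        sig = self.significant
        lines = [
            "Hotspot model results",
            "=" * 60,
            f"tests: {len(self.table)}   significant (BY q < {self.fdr:g}): {len(sig)}",
            "-" * 60,
        ]
        show = sig if len(sig) else self.table.head(10)
        lines.append(show.to_string(index=False))
        return "\n".join(lines)
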