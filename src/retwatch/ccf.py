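"""Cancer cell fraction (CCF) estimation and clonality classification.

The fraction of tumor cells carrying a somatic mutation is inferred from the
observed mutant allele fraction (MAF), the locus-specific sequencing depth,
the tumor purity and the allele-specific copy number at the locus.  For a
mutation present at multiplicity ``m`` (mutant copies per tumor cell) in a
tumor of purity ``rho`` with total copy number ``tcn``, the expected variant
allele fraction is

    v(ccf) = rho * m * ccf / (rho * tcn + 2 * (1 - rho))

The alt read count is modelled as Binomial(depth, v(ccf)); the CCF is
estimated by maximum likelihood on a discrete grid and the 95% interval is
the central mass of the grid-normalised likelihood (a posterior under a
uniform prior).  A mutation is *clonal* when the upper bound of its 95%
interval exceeds 0.85, otherwise *subclonal*; a tumor shows significant
subclonal heterogeneity when more than 30% of its non-synonymous mutations
are subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CcfEstimate",
    "CopyState",
    "HeterogeneityCall",
    "expected_vaf",
    "estimate_ccf",
    "classify_clonality",
    "assess_heterogeneity",
    "compute_tmb_and_msi",
    "CcfModel",
    "CcfResults",
    "CCF_GRID",
    "CLONAL_CI_THRESHOLD",
    "HETEROGENEITY_THRESHOLD",
]

#: CCF grid: 100 points at 0.01 resolution, starting at 0.01 (a mutation
#: observed with >=1 alt read has nonzero CCF, so 0 is excluded).
CCF_GRID = np.arange(1, 101) / 100.0

#: A mutation is clonal when the 95% CI upper bound is strictly > this.
CLONAL_CI_THRESHOLD = 0.85

#: A tumor is heterogeneous when the subclonal fraction is strictly > this.
HETEROGENEITY_THRESHOLD = 0.30


class CcfEstimationError(ValueError):
    """Raised when a CCF cannot be estimated (zero depth, zero copies...)."""


@dataclass(frozen=True)
class CopyState:
    """Allele-specific copy number at a locus (FACETS-style output)."""

    tcn: int
    lcn: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tcn < 0:
            raise ValueError(f"tcn must be >= 0, got {self.tcn}")
        if self.lcn is not None and not (0 <= self.lcn <= self.tcn):
            raise ValueError(f"lcn must lie in [0, tcn], got lcn={self.lcn}, tcn={self.tcn}")


@dataclass(frozen=True)
class CcfEstimate:
    """Point estimate of a mutation's cancer cell fraction with 95% interval."""

    ccf_hat: float
    ci_low: float
    ci_high: float
    multiplicity: int
    clonal: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ccf_hat <= self.ci_high):
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class HeterogeneityCall:
    """Per-sample subclonal heterogeneity summary over non-synonymous mutations."""

    n_subclonal: int
    n_total: int
    subclonal_fraction: float
    heterogeneous: bool


def expected_vaf(ccf: float, purity: float, tcn: int, m: int) -> float:
    """Expected variant allele fraction for a mutation at CCF ``ccf``.

    Parameters
    ----------
    ccf : fraction of tumor cells carrying the mutation, in [0, 1].
    purity : tumor cell fraction of the sample, in (0, 1].
    tcn : total copy number at the locus in tumor cells (>= 1 when m >= 1).
    m : mutant copies per mutated tumor cell (1 <= m <= tcn).

    Returns
    -------
    float
        ``purity * m * ccf / (purity * tcn + 2 * (1 - purity))``, in [0, 1].
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"ccf must be in [0, 1], got {ccf}")
    if m < 1 or tcn < 1:
        raise ValueError(f"need m >= 1 and tcn >= 1, got m={m}, tcn={tcn}")
    if m > tcn:
        raise ValueError(f"multiplicity {m} exceeds total copy number {tcn}")
    return purity * m * ccf / (purity * tcn + 2.0 * (1.0 - purity))


def _select_multiplicity(maf: float, purity: float, tcn: int) -> int:
    # Rounded mutant-copy estimate, clipped to [1, tcn]. The naive
    # all-m likelihood scan is degenerate: noise pushing the MAF above the
    # m=1 ceiling flips truncal calls to (m=2, ccf~0.5).
    denom = purity * tcn + 2.0 * (1.0 - purity)
    m = int(round(maf * denom / purity))
    return max(1, min(tcn, m))


def estimate_ccf(
    t_alt_count: int,
    t_depth: int,
    purity: float,
    copy_state: CopyState | tuple[int, Optional[int]] = CopyState(2, 1),
) -> CcfEstimate:
    """Estimate the CCF of one mutation by binomial maximum likelihood.

    The multiplicity is the rounded mutant-copy estimate
    ``clip(round(maf * D / purity), 1, tcn)`` with ``D = purity*tcn + 2(1-purity)``.
    The CCF is the grid argmax of ``Binom(alt; depth, expected_vaf(ccf))`` over
    {0.01, ..., 1.00}; the interval is the central 95% of the grid-normalised
    likelihood.

    Raises
    ------
    CcfEstimationError
        If ``t_depth == 0`` (no reads) or ``tcn == 0`` (no allele to mutate).
    """
    if isinstance(copy_state, tuple):
        copy_state = CopyState(*copy_state)
    if t_depth < 1:
        raise CcfEstimationError("cannot estimate CCF at zero depth")
    if copy_state.tcn < 1:
        raise CcfEstimationError("cannot estimate CCF with zero copies (tcn=0)")
    if not 0 <= t_alt_count <= t_depth:
        raise ValueError("t_alt_count must lie in [0, t_depth]")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")

    tcn = copy_state.tcn
    maf = t_alt_count / t_depth
    m = _select_multiplicity(maf, purity, tcn)

    denom = purity * tcn + 2.0 * (1.0 - purity)
    vaf_grid = np.minimum(1.0, purity * m * CCF_GRID / denom)
    loglik = stats.binom.logpmf(t_alt_count, t_depth, vaf_grid)
    posterior = np.exp(loglik - loglik.max())
    posterior /= posterior.sum()

    ccf_hat = float(CCF_GRID[int(np.argmax(posterior))])
    # Highest-posterior-density 95% set: smallest collection of grid points
    # reaching 0.95 mass. An equal-tailed interval systematically excludes
    # the boundary for truncal mutations (the renormalised upper quantile
    # falls below 1.0), so HPD is used; the posterior is unimodal, making
    # the selected set an interval containing the mode.
    order = np.argsort(-posterior, kind="stable")
    n_keep = int(np.searchsorted(np.cumsum(posterior[order]), 0.95)) + 1
    kept = order[:n_keep]
    ci_low = float(CCF_GRID[kept.min()])
    ci_high = float(CCF_GRID[kept.max()])

    return CcfEstimate(
        ccf_hat=ccf_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        multiplicity=m,
        clonal=ci_high > CLONAL_CI_THRESHOLD,
    )


def classify_clonality(estimate: CcfEstimate) -> str:
    """Return ``"clonal"`` if the 95% CI upper bound is strictly > 0.85, else ``"subclonal"``."""
    return "clonal" if estimate.ci_high > CLONAL_CI_THRESHOLD else "subclonal"


def assess_heterogeneity(estimates: Sequence[CcfEstimate]) -> HeterogeneityCall:
    """Assess subclonal heterogeneity over a sample's non-synonymous mutations.

    A tumor is heterogeneous when strictly more than 30% of its (non-synonymous)
    mutations are subclonal. The caller is responsible for restricting the input
    to non-synonymous mutations.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one CCF estimate")
    n_sub = sum(1 for e in estimates if classify_clonality(e) == "subclonal")
    frac = n_sub / len(estimates)
    return HeterogeneityCall(
        n_subclonal=n_sub,
        n_total=len(estimates),
        subclonal_fraction=frac,
        heterogeneous=frac > HETEROGENEITY_THRESHOLD,
    )


def compute_tmb_and_msi(
    n_nonsyn: int, panel_mb: float, msi_score: Optional[float] = None
) -> tuple[float, str]:
    """Tumor mutational burden (non-synonymous mutations / Mb) and MSI category.

    MSIsensor scores < 10 are microsatellite stable (MSS), > 10 MSI-high;
    a score of exactly 10 falls in neither published band and is reported
    as ``indeterminate``. A missing score yields ``not_assessed``.
    """
    if panel_mb <= 0:
        raise ValueError(f"panel size must be positive, got {panel_mb}")
    tmb = n_nonsyn / panel_mb
    if msi_score is None:
        msi = "not_assessed"
    elif msi_score < 10:
        msi = "MSS"
    elif msi_score > 10:
        msi = "MSI-H"
    else:
        msi = "indeterminate"
    return tmb, msi


class CcfModel:
    """Binomial CCF model over a table of somatic variants from one sample.

    Parameters
    ----------
    data : DataFrame with columns ``t_alt_count``, ``t_depth`` and optionally
        ``tcn``, ``lcn`` (default diploid heterozygous: tcn=2, lcn=1) and
        ``nonsynonymous`` (default True).
    purity : tumor purity in (0, 1].

    Examples
    --------
    >>> model = CcfModel.from_dataframe(maf_df, purity=0.6)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, data: pd.DataFrame, purity: float):
        if not 0.0 < purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {purity}")
        required = {"t_alt_count", "t_depth"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True).copy()
        if "tcn" not in self.data:
            self.data["tcn"] = 2
        if "lcn" not in self.data:
            self.data["lcn"] = 1
        if "nonsynonymous" not in self.data:
            self.data["nonsynonymous"] = True
        self.purity = float(purity)

    @classmethod
    def from_dataframe(
        cls,
        variants: pd.DataFrame,
        purity: float,
        copy_states: Optional[pd.DataFrame] = None,
    ) -> "CcfModel":
        """Build from a MAF-like variant table, optionally joining a copy-state table.

        ``copy_states`` carries segment columns (chrom, start, end, tcn, lcn);
        each variant is assigned the copy state of the segment containing its
        position (variants outside all segments default to tcn=2, lcn=1).
        """
        df = variants.copy()
        if copy_states is not None and len(copy_states):
            tcn = np.full(len(df), 2, dtype=int)
            lcn = np.full(len(df), 1, dtype=int)
            for _, seg in copy_states.iterrows():
                hit = (
                    (df["chrom"].astype(str) == str(seg["chrom"]))
                    & (df["pos"] >= seg["start"])
                    & (df["pos"] <= seg["end"])
                ).to_numpy()
                tcn[hit] = int(seg["tcn"])
                lcn[hit] = int(seg["lcn"])
            df["tcn"] = tcn
            df["lcn"] = lcn
        return cls(df, purity=purity)

    def fit(self) -> "CcfResults":
        rows = []
        for _, row in self.data.iterrows():
            est = estimate_ccf(
                int(row["t_alt_count"]),
                int(row["t_depth"]),
                self.purity,
                CopyState(int(row["tcn"]), int(row["lcn"]) if pd.notna(row["lcn"]) else None),
            )
            rows.append(
                {
                    "m": est.multiplicity,
                    "ccf_hat": est.ccf_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "clonal": est.clonal,
                }
            )
        frame = pd.concat([self.data, pd.DataFrame(rows, index=self.data.index)], axis=1)
        return CcfResults(self, frame)


class CcfResults:
    """Fitted per-variant CCF estimates with clonality and heterogeneity views."""

    def __init__(self, model: CcfModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def estimates(self) -> list[CcfEstimate]:
        return [
            CcfEstimate(r.ccf_hat, r.ci_low, r.ci_high, int(r.m), bool(r.clonal))
            for r in self.frame.itertuples()
        ]

    def heterogeneity(self) -> HeterogeneityCall:
        nonsyn = self.frame[self.frame["nonsynonymous"].astype(bool)]
        ests = [
            CcfEstimate(r.ccf_hat, r.ci_low, r.ci_high, int(r.m), bool(r.clonal))
            for r in nonsyn.itertuples()
        ]
        return assess_heterogeneity(ests)

    def summary(self) -> str:
        het = self.heterogeneity()
        n_clonal = int(self.frame["clonal"].sum())
        lines = [
            "CCF model results",
            "=" * 60,
            f"variants: {len(self.frame)}   purity: {self.model.purity:.2f}",
            f"clonal: {n_clonal}   subclonal: {len(self.frame) - n_clonal}",
            (
                f"subclonal fraction (non-syn): {het.subclonal_fraction:.2f} "
                f"-> {'heterogeneous' if het.heterogeneous else 'homogeneous'}"
            ),
            "-" * 60,
        ]
        cols = [c for c in ("variant_id", "gene", "t_alt_count", "t_depth",
                            "m", "ccf_hat", "ci_low", "ci_high", "clonal")
                if c in self.frame.columns]
        lines.append(self.frame[cols].to_string(index=False))
        return "\n".join(lines)
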