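"""Longitudinal ctDNA trajectories, shedding, emergence, subclone grouping.

A patient's plasma calls across timepoints form per-variant allele-fraction
trajectories. This module classifies baseline ctDNA shedding, quantifies the
on-treatment reduction of the enrolling alteration, detects alterations that
emerge on therapy, and groups tracked variants into inferred subclonal cell
populations by the concordance of their trajectory dynamics with min/max
allele-fraction envelopes per population.

Trajectories are long-format DataFrames with one row per (variant, day) and
columns ``variant_id``, ``day``, ``af``, ``passed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .duplex import LOD_AF, PlasmaVariantCall

__all__ = [
    "SubcloneAssignment",
    "percent_reduction",
    "classify_shedding",
    "detect_emergent",
    "assign_subclones",
    "membership_accuracy",
    "MINIMAL_SHEDDING_AF",
]

#: AF cap for "minimal" shedding, from the observed 0.1-0.8% range in
#: discordant baseline samples. A heuristic operating point, not a rule of
#: the assay.
MINIMAL_SHEDDING_AF = 0.008


@dataclass
class SubcloneAssignment:
    """An inferred cell population: member variants plus AF envelopes."""

    subclone_id: str
    members: list[str]
    #: day -> (min observed af, max observed af) over members
    envelope: dict[float, tuple[float, float]]
    contains_driver: bool = False


def membership_accuracy(
    subclones: Sequence[SubcloneAssignment], truth: dict[str, str]
) -> float:
    """Fraction of variants assigned to the correct population.

    Inferred subclones are matched to true clone labels greedily by overlap
    (largest shared member set first, each side used once); variants in a
    matched pair count as correct.
    """
    if not truth:
        raise ValueError("empty truth labelling")
    overlaps = []
    for sc in subclones:
        members = [v for v in sc.members if v in truth]
        counts: dict[str, int] = {}
        for v in members:
            counts[truth[v]] = counts.get(truth[v], 0) + 1
        for label, c in counts.items():
            overlaps.append((c, sc.subclone_id, label))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_sc: set[str] = set()
    used_label: set[str] = set()
    correct = 0
    for c, sc_id, label in overlaps:
        if sc_id in used_sc or label in used_label:
            continue
        used_sc.add(sc_id)
        used_label.add(label)
        correct += c
    return correct / len(truth)


def percent_reduction(baseline_af: float, later_af: float) -> float:
    """Percent reduction in allele fraction from baseline (negative = increase)."""
    if baseline_af <= 0:
        raise ValueError("baseline allele fraction must be positive")
    return 100.0 * (baseline_af - later_af) / baseline_af


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    rows = [
        {"variant_id": c.variant_id, "af": c.af, "passed": c.passed}
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["variant_id", "af", "passed"])


def classify_shedding(baseline_calls, enrolling_variant: str) -> str:
    """Classify baseline ctDNA shedding: ``shedding``, ``minimal`` or ``none``.

    A sample sheds when the enrolling alteration is detected (or other somatic
    alterations are detected at appreciable levels); it sheds minimally when
    the enrolling alteration is absent but 1-3 other somatic calls pass, all
    at allele fractions <= 0.8%; it is a non-shedder when nothing passes at
    the assay's limit of detection.
    """
    df = _calls_frame(baseline_calls)
    if len(df) == 0:
        raise ValueError("baseline timepoint has no calls to classify")
    passed = df[df["passed"].astype(bool)]
    if (passed["variant_id"] == enrolling_variant).any():
        return "shedding"
    if len(passed) == 0:
        return "none"
    others = passed[passed["variant_id"] != enrolling_variant]
    if 1 <= len(others) <= 3 and (others["af"] <= MINIMAL_SHEDDING_AF).all():
        return "minimal"
    return "shedding"


def _check_trajectories(traj: pd.DataFrame) -> list[float]:
    required = {"variant_id", "day", "af", "passed"}
    missing = required - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    days = sorted(traj["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two timepoints")
    return days


def detect_emergent(traj: pd.DataFrame) -> list[str]:
    """Variants not detected at baseline that pass at a later timepoint."""
    days = _check_trajectories(traj)
    baseline = days[0]
    out = []
    for vid, sub in traj.groupby("variant_id", sort=True):
        at_base = sub[sub["day"] == baseline]
        passed_base = bool(at_base["passed"].any()) if len(at_base) else False
        passed_later = bool(sub[(sub["day"] > baseline) & sub["passed"].astype(bool)].shape[0])
        if not passed_base and passed_later:
            out.append(vid)
    return out


def _sign_series(
    afs: np.ndarray, quant: np.ndarray, dead_band: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval change signs (-1/0/+1) and a validity mask.

    Below-LOD points count as af 0 for sign purposes; an interval is valid
    only when the variant is quantifiable at both endpoints. Changes smaller
    than ``dead_band`` x the variant's first quantifiable af count as zero.
    """
    base_idx = np.nonzero(quant)[0]
    baseline_af = afs[base_idx[0]] if len(base_idx) else 0.0
    eff = np.where(quant, afs, 0.0)
    delta = np.diff(eff)
    signs = np.sign(delta)
    signs[np.abs(delta) < dead_band * baseline_af] = 0
    valid = quant[:-1] & quant[1:]
    return signs.astype(int), valid


def _concordant(sa, va, sb, vb) -> tuple[bool, bool]:
    """(concordant over shared valid intervals, any shared interval exists)."""
    shared = va & vb
    if not shared.any():
        return True, False
    agree = (sa[shared] == sb[shared]) | (sa[shared] == 0) | (sb[shared] == 0)
    return bool(agree.all()), True


def assign_subclones(
    traj: pd.DataFrame,
    driver: str,
    lod: float = LOD_AF,
    dead_band: float = 0.1,
) -> list[SubcloneAssignment]:
    """Group tracked variants into inferred subclonal populations.

    Deterministic rule set: (1) the driver seeds subclone 1; (2) a variant
    joins subclone 1 when, over every interval where both it and the driver
    are quantifiable (passed or af >= LOD), the signs of their AF changes
    agree (a change within the dead band counts as zero and agrees with
    anything) — a variant sharing no quantifiable interval with the driver is
    deferred to step 3 unless it was quantifiable at baseline alongside the
    driver; (3) remaining variants are grouped by first-emergence timepoint
    and pairwise sign concordance (connected components); (4) per-timepoint
    min/max envelopes are computed over members' observed AFs.
    """
    days = _check_trajectories(traj)
    wide_af = traj.pivot_table(index="variant_id", columns="day", values="af", aggfunc="first")
    wide_af = wide_af.reindex(columns=days).fillna(0.0)
    wide_pass = traj.pivot_table(
        index="variant_id", columns="day", values="passed", aggfunc="first"
    ).reindex(columns=days).fillna(False).astype(bool)
    if driver not in wide_af.index:
        raise ValueError(f"driver {driver!r} absent from trajectories")

    variants = list(wide_af.index)
    signs: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    quant: dict[str, np.ndarray] = {}
    emergence: dict[str, Optional[float]] = {}
    for v in variants:
        afs = wide_af.loc[v].to_numpy(dtype=float)
        q = wide_pass.loc[v].to_numpy() | (afs >= lod)
        s, m = _sign_series(afs, q, dead_band)
        signs[v], valid[v], quant[v] = s, m, q
        idx = np.nonzero(q)[0]
        emergence[v] = days[idx[0]] if len(idx) else None

    # (1)-(2): driver clone
    clone1 = [driver]
    rest = []
    for v in variants:
        if v == driver:
            continue
        agree, comparable = _concordant(signs[v], valid[v], signs[driver], valid[driver])
        co_baseline = bool(quant[v][0] and quant[driver][0])
        if agree and (comparable or co_baseline):
            clone1.append(v)
        else:
            rest.append(v)

    # (3): group the rest by emergence day, then sign concordance within group
    groups: list[list[str]] = []
    by_day: dict[Optional[float], list[str]] = {}
    for v in rest:
        by_day.setdefault(emergence[v], []).append(v)
    for day in sorted(by_day, key=lambda d: (d is None, d)):
        members = by_day[day]
        comps: list[list[str]] = []
        for v in members:
            placed = False
            for comp in comps:
                if all(_concordant(signs[v], valid[v], signs[w], valid[w])[0] for comp_w in [comp] for w in comp_w):
                    comp.append(v)
                    placed = True
                    break
            if not placed:
                comps.append([v])
        groups.extend(comps)

    def _envelope(members: list[str]) -> dict[float, tuple[float, float]]:
        sub = wide_af.loc[members]
        return {
            float(d): (float(sub[d].min()), float(sub[d].max())) for d in days
        }

    out = [
        SubcloneAssignment(
            subclone_id="subclone_1",
            members=sorted(clone1),
            envelope=_envelope(clone1),
            contains_driver=True,
        )
    ]
    for i, members in enumerate(groups, start=2):
        out.append(
            SubcloneAssignment(
                subclone_id=f"subclone_{i}",
                members=sorted(members),
                envelope=_envelope(members),
            )
        )
    return out
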