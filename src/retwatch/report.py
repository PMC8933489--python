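"""Variant annotation, resistance-mechanism classification, cohort metrics.

A bundled, versioned knowledge table (TSV, no network access) maps alleles
and residue classes to functional categories: RET on-target resistance
residues (solvent front G810, gatekeeper V804, pocket roof Y806), known
activating alleles, RAS/BRAF oncogenic classes and amplification targets
(MET, FGFR1). Per-patient mechanism calls combine annotated emergent
variants, subclone assignments and read-backed phasing into the study's
taxonomy: on-target secondary RET mutations (including cis compound
alleles), bypass mutations or amplifications, primary RAS-driven resistance,
or none identified — with a polyclonal flag when independent subclones carry
distinct mechanism-bearing alterations.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .duplex import PhasingResult
from .dynamics import SubcloneAssignment, detect_emergent, percent_reduction

__all__ = [
    "KnowledgeTable",
    "load_knowledge_table",
    "annotate_variant",
    "MechanismCall",
    "classify_mechanisms",
    "PatientOutcome",
    "cohort_metrics",
    "load_synthetic_baseline_cohort",
]

_PCHANGE_RE = re.compile(
    r"^(?:p\.)?([A-Z])(\d+)(?:([A-Z])|(del|dup|ins|fs).*)?$", re.IGNORECASE
)

RAS_BRAF_GENES = {"KRAS", "NRAS", "BRAF"}
ON_TARGET_CATEGORIES = {"solvent_front", "gatekeeper", "roof"}


def _parse_protein_change(protein_change: str) -> tuple[str, int, Optional[str]]:
    """Parse 'p.V804M' / 'G12V' / 'A59del' into (ref_aa, residue, alt or None)."""
    m = _PCHANGE_RE.match(str(protein_change).strip())
    if not m:
        raise ValueError(f"cannot parse protein change {protein_change!r}")
    ref, pos, alt, special = m.groups()
    return ref.upper(), int(pos), (alt.upper() if alt else None)


class KnowledgeTable:
    """Allele/residue-class -> category lookup backed by the bundled TSV."""

    def __init__(self, frame: pd.DataFrame):
        required = {"gene", "allele", "category"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"knowledge table missing columns: {sorted(missing)}")
        self.frame = frame.copy()
        self._exact: dict[tuple[str, str], str] = {}
        self._residue: dict[tuple[str, str], str] = {}
        self._gene: dict[str, str] = {}
        for r in frame.itertuples():
            gene = str(r.gene)
            allele = str(r.allele)
            if allele == "*":
                self._gene[gene] = r.category
            elif allele.endswith("*"):
                self._residue[(gene, allele[:-1])] = r.category
            else:
                self._exact[(gene, allele)] = r.category

    def lookup(self, gene: str, protein_change: Optional[str],
               is_amplification: bool = False) -> list[str]:
        """Category tags for one alteration; exact allele beats residue class."""
        tags: list[str] = []
        if is_amplification:
            cat = self._gene.get(gene)
            if cat is not None:
                tags.append(cat)
            return tags
        if protein_change is None or str(protein_change) in ("", "nan"):
            return tags
        ref, pos, alt = _parse_protein_change(protein_change)
        allele = f"{ref}{pos}{alt}" if alt else f"{ref}{pos}del"
        if (gene, allele) in self._exact:
            tags.append(self._exact[(gene, allele)])
        elif (gene, f"{ref}{pos}") in self._residue:
            tags.append(self._residue[(gene, f"{ref}{pos}")])
        elif gene in self._gene:
            tags.append(self._gene[gene])
        return tags


def load_synthetic_baseline_cohort() -> pd.DataFrame:
    """Synthetic baseline cohort encoding the published plasma detection tallies.

    One row per patient with ret_class (mutant / fusion), baseline_detected
    and placeholder outcome columns. Detection counts match the published
    study-level tallies (18/19 mutant, 36/49 fusion); everything else is a
    synthetic stand-in, not patient data.
    """
    with resources.files("retwatch.data").joinpath("synthetic_baseline_cohort.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_knowledge_table(path: Optional[str | Path] = None) -> KnowledgeTable:
    """Load the bundled knowledge table (or a custom TSV at ``path``)."""
    if path is None:
        with resources.files("retwatch.data").joinpath("knowledge.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    return KnowledgeTable(frame)


def annotate_variant(
    gene: str,
    protein_change: Optional[str],
    knowledge: Optional[KnowledgeTable] = None,
    is_amplification: bool = False,
) -> list[str]:
    """Annotate one alteration with knowledge-table category tags."""
    knowledge = knowledge or load_knowledge_table()
    return knowledge.lookup(gene, protein_change, is_amplification=is_amplification)


@dataclass
class MechanismCall:
    """Per-patient resistance mechanism classification with evidence."""

    patient: str
    mechanisms: frozenset[str]
    polyclonal: bool
    cis_compound: Optional[str] = None
    evidence: list[dict] = field(default_factory=list)


def _subclone_of(variant: str, subclones: Optional[Sequence[SubcloneAssignment]]) -> Optional[str]:
    if not subclones:
        return None
    for sc in subclones:
        if variant in sc.members:
            return sc.subclone_id
    return None


def classify_mechanisms(
    trajectories: pd.DataFrame,
    driver: str,
    knowledge: Optional[KnowledgeTable] = None,
    subclones: Optional[Sequence[SubcloneAssignment]] = None,
    phasing: Optional[Sequence[PhasingResult]] = None,
    patient: str = "patient",
) -> MechanismCall:
    """Classify a progressing patient's resistance mechanism(s).

    ``trajectories`` is long-format per (variant, day) with columns
    variant_id, day, af, passed, gene, protein_change and optionally
    is_amplification. Rules (set semantics, mechanisms may co-occur):

    a. an emergent RET allele at a solvent-front / gatekeeper / roof residue
       is on-target secondary resistance; a roof + gatekeeper pair phased in
       cis is additionally reported as a compound allele;
    b. an emergent oncogenic-activating RAS or BRAF allele is a bypass
       mutation;
    c. an emergent amplification of an amplification-target gene is bypass
       amplification;
    d. a baseline oncogenic RAS allele whose trajectory rises while the
       driver falls marks primary RAS-driven resistance;
    e. if no rule fires the mechanism is none_identified.

    The call is polyclonal when two or more mechanism-bearing variants sit in
    distinct subclones. Evidence variants without a subclone assignment are
    classified but flagged unphased.
    """
    knowledge = knowledge or load_knowledge_table()
    required = {"variant_id", "day", "af", "passed", "gene", "protein_change"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    traj = trajectories.copy()
    if "is_amplification" not in traj:
        traj["is_amplification"] = False
    days = sorted(traj["day"].unique())
    baseline = days[0]
    emergent = set(detect_emergent(traj))

    meta = traj.drop_duplicates("variant_id").set_index("variant_id")
    mechanisms: set[str] = set()
    evidence: list[dict] = []
    on_target_alleles: dict[str, str] = {}  # category -> allele string

    def _first_passed_day(vid: str) -> Optional[float]:
        sub = traj[(traj["variant_id"] == vid) & traj["passed"].astype(bool)]
        return float(sub["day"].min()) if len(sub) else None

    def _add_evidence(vid: str, mechanism: str) -> None:
        sc = _subclone_of(vid, subclones)
        evidence.append(
            {
                "variant": vid,
                "mechanism": mechanism,
                "timepoint": _first_passed_day(vid),
                "subclone": sc,
                "unphased": sc is None,
            }
        )

    for vid in sorted(set(traj["variant_id"])):
        gene = str(meta.loc[vid, "gene"])
        pchange = meta.loc[vid, "protein_change"]
        is_amp = bool(meta.loc[vid, "is_amplification"])
        tags = knowledge.lookup(gene, None if is_amp else pchange, is_amplification=is_amp)
        if vid in emergent:
            if gene == "RET" and any(t in ON_TARGET_CATEGORIES for t in tags):
                mechanisms.add("on_target_secondary")
                _add_evidence(vid, "on_target_secondary")
                for t in tags:
                    if t in ON_TARGET_CATEGORIES:
                        on_target_alleles[t] = str(pchange)
            if gene in RAS_BRAF_GENES and "oncogenic_activating" in tags:
                mechanisms.add("bypass_mutation")
                _add_evidence(vid, "bypass_mutation")
            if is_amp and "amplification_target" in tags:
                mechanisms.add("bypass_amplification")
                _add_evidence(vid, "bypass_amplification")

    # (d) primary resistance: baseline RAS allele rising while the driver falls
    def _traj_of(vid: str) -> pd.DataFrame:
        return traj[traj["variant_id"] == vid].sort_values("day")

    drv = _traj_of(driver)
    if len(drv) >= 2:
        driver_falls = float(drv["af"].iloc[-1]) < float(drv["af"].iloc[0])
        for vid in sorted(set(traj["variant_id"])):
            if vid == driver or vid in emergent:
                continue
            gene = str(meta.loc[vid, "gene"])
            if gene not in (RAS_BRAF_GENES - {"BRAF"}):
                continue
            tags = knowledge.lookup(gene, meta.loc[vid, "protein_change"])
            sub = _traj_of(vid)
            at_base = sub[sub["day"] == baseline]
            passed_base = bool(at_base["passed"].any()) if len(at_base) else False
            if "oncogenic_activating" in tags and passed_base and len(sub) >= 2:
                rises = float(sub["af"].iloc[-1]) > float(sub["af"].iloc[0])
                if rises and driver_falls:
                    mechanisms.add("primary_ras")
                    _add_evidence(vid, "primary_ras")

    # gatekeeper + roof phased in cis -> compound allele
    cis_compound = None
    if "gatekeeper" in on_target_alleles or "roof" in on_target_alleles:
        gk = on_target_alleles.get("gatekeeper")
        roof = on_target_alleles.get("roof")
        # the pre-existing partner may be a baseline (non-emergent) allele
        for vid in sorted(set(traj["variant_id"])):
            gene = str(meta.loc[vid, "gene"])
            if gene != "RET":
                continue
            tags = knowledge.lookup(gene, meta.loc[vid, "protein_change"])
            if "gatekeeper" in tags and gk is None:
                gk = str(meta.loc[vid, "protein_change"])
            if "roof" in tags and roof is None:
                roof = str(meta.loc[vid, "protein_change"])
        if gk and roof and phasing:
            def _clean(s: str) -> str:
                return str(s).removeprefix("p.")
            for ph in phasing:
                pair = {ph.variant_a, ph.variant_b}
                named = {_clean(gk), _clean(roof)}
                if ph.call == "cis" and {_clean(x) for x in pair} == named:
                    cis_compound = f"{_clean(gk)}/{_clean(roof)}"
                    mechanisms.add("on_target_secondary")

    if not mechanisms:
        mechanisms = {"none_identified"}

    bearing = {e["variant"]: e["subclone"] for e in evidence}
    distinct = {sc for sc in bearing.values() if sc is not None}
    polyclonal = len(bearing) >= 2 and len(distinct) >= 2

    return MechanismCall(
        patient=patient,
        mechanisms=frozenset(mechanisms),
        polyclonal=polyclonal,
        cis_compound=cis_compound,
        evidence=evidence,
    )


@dataclass(frozen=True)
class PatientOutcome:
    """Best response and its duration for one patient."""

    best_response: str  # CR | PR | SD | PD
    duration_weeks: float
    on_treatment: bool = False

    @property
    def clinical_benefit(self) -> bool:
        """SD/PR/CR lasting >= 24 weeks, or ongoing treatment with SD/PR/CR."""
        return self.best_response in {"SD", "PR", "CR"} and (
            self.duration_weeks >= 24.0 or self.on_treatment
        )


def _ceil_percent(k: int, n: int) -> int:
    # rates are reported to the next whole percent
    return int(math.ceil(100.0 * k / n)) if n else 0


def cohort_metrics(patients: pd.DataFrame) -> dict:
    """Cohort-level report: detection rates, clinical benefit, reductions.

    ``patients`` has one row per patient with columns ret_class
    ('mutant'/'fusion'), baseline_detected (bool), best_response,
    duration_weeks, on_treatment, and optionally percent_reduction and
    mechanisms (iterable of mechanism labels).

    Returns a dict with per-class plasma detection rates (whole percent),
    the clinical benefit rate, the median percent reduction of the enrolling
    alteration, and mechanism tallies.
    """
    if len(patients) == 0:
        raise ValueError("empty cohort")
    report: dict = {"n_patients": int(len(patients)), "detection_rate": {}}
    for cls, sub in patients.groupby("ret_class"):
        k = int(sub["baseline_detected"].astype(bool).sum())
        report["detection_rate"][cls] = {
            "detected": k,
            "total": int(len(sub)),
            "percent": _ceil_percent(k, len(sub)),
        }
    outcomes = [
        PatientOutcome(str(r.best_response), float(r.duration_weeks),
                       bool(getattr(r, "on_treatment", False)))
        for r in patients.itertuples()
    ]
    n_benefit = sum(1 for o in outcomes if o.clinical_benefit)
    report["clinical_benefit"] = {
        "n": n_benefit,
        "total": len(outcomes),
        "percent": _ceil_percent(n_benefit, len(outcomes)),
    }
    if "percent_reduction" in patients.columns:
        vals = patients["percent_reduction"].dropna()
        report["median_percent_reduction"] = float(np.median(vals)) if len(vals) else None
    if "mechanisms" in patients.columns:
        tally: dict[str, int] = {}
        for mechs in patients["mechanisms"].dropna():
            for m in mechs:
                tally[m] = tally.get(m, 0) + 1
        report["mechanism_tally"] = tally
    return report
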