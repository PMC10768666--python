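"""Host-fungal metabolome overlap statistics and class summaries.

"Shared" is always defined on the replicate-backed presence calls of the
feature tables: a feature counts as shared when it is present (>= 2 of 3
replicates) in at least one host sample AND at least one fungal strain
sample. Percentages reproduce printed-report arithmetic with a single fixed
rounding rule (half-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable, HOST_TYPES
from .msnet import MolecularNetwork


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), the rule used for all reported
    percentages; ndigits=0 returns a float with no decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """100 * numerator / denominator, rounded half-up to ndigits decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


# --------------------------------------------------------------------------
# Overlap
# --------------------------------------------------------------------------

@dataclass
class OverlapReport:
    n_total: int
    n_host_only: int
    n_fungal_only: int
    n_shared: int
    pct_shared: float
    shared_ids: list[str] = field(default_factory=list)
    n_shared_clusters: Optional[int] = None
    per_strain: dict[str, tuple[int, float]] = field(default_factory=dict)
    crude_vs_fractions: Optional[dict] = None

    def __post_init__(self):
        if self.n_host_only + self.n_fungal_only + self.n_shared != self.n_total:
            raise ValueError("overlap counts violate inclusion-exclusion")

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total, "n_host_only": self.n_host_only,
            "n_fungal_only": self.n_fungal_only, "n_shared": self.n_shared,
            "pct_shared": self.pct_shared,
            "n_shared_clusters": self.n_shared_clusters,
            "per_strain": {k: {"n_shared": n, "pct": p}
                           for k, (n, p) in self.per_strain.items()},
            "crude_vs_fractions": self.crude_vs_fractions,
        }
        return d


def _presence_calls(table: FeatureTable, types) -> pd.Series:
    if table.presence is None:
        raise ValueError("table lacks presence calls; run filter_replicates first")
    samples = table.samples_of_type(types)
    return table.presence[samples].any(axis=1)


def shared_features(host_table: FeatureTable, fungal_table: FeatureTable,
                    ndigits: int = 0):
    """Features present in >= 1 host sample AND >= 1 fungal sample.

    Returns (n_shared, pct of the union total, sorted shared ids). The two
    tables must share a feature-id space (rows aligned in the same run).
    """
    host_ids = set(host_table.features.index)
    fungal_ids = set(fungal_table.features.index)
    # tables from different runs have unrelated id spaces AND unrelated
    # metadata; genuinely zero-overlap splits of one run share their metadata
    if (host_ids and fungal_ids and host_ids.isdisjoint(fungal_ids)
            and not host_table.meta.equals(fungal_table.meta)):
        raise ValueError("host and fungal tables have disjoint feature id spaces; "
                         "were they produced by the same alignment run?")
    host_present = _presence_calls(host_table, HOST_TYPES)
    fungal_present = _presence_calls(fungal_table, {"fungal"})
    shared = sorted(host_ids & fungal_ids
                    & set(host_present.index[host_present])
                    & set(fungal_present.index[fungal_present]))
    n_total = len(host_ids | fungal_ids)
    pct = percentage(len(shared), n_total, ndigits) if n_total else 0.0
    return len(shared), pct, shared


def overlap_report(host_table: FeatureTable, fungal_table: FeatureTable,
                   network: Optional[MolecularNetwork] = None,
                   ndigits: int = 0) -> OverlapReport:
    n_shared, pct, ids = shared_features(host_table, fungal_table, ndigits)
    host_ids = set(host_table.features.index)
    fungal_ids = set(fungal_table.features.index)
    n_total = len(host_ids | fungal_ids)
    report = OverlapReport(
        n_total=n_total,
        n_host_only=len(host_ids - fungal_ids),
        n_fungal_only=len(fungal_ids - host_ids),
        n_shared=len(host_ids & fungal_ids),
        pct_shared=pct, shared_ids=ids)
    if network is not None:
        n_sc, _ = shared_clusters(network, host_ids, fungal_ids)
        report.n_shared_clusters = n_sc
    report.per_strain = per_strain_overlap(fungal_table, host_table)
    return report


def shared_clusters(network: MolecularNetwork, host_ids, fungal_ids):
    """Molecular families containing >= 1 host-side node and >= 1
    fungal-side node (one node present on both sides suffices)."""
    host_ids, fungal_ids = set(host_ids), set(fungal_ids)
    shared_fams = []
    for fam, members in network.family_members().items():
        if members & host_ids and members & fungal_ids:
            shared_fams.append(fam)
    return len(shared_fams), sorted(shared_fams)


def per_strain_overlap(fungal_table: FeatureTable, host_table: FeatureTable,
                       ndigits: int = 0) -> dict[str, tuple[Optional[int], Optional[float]]]:
    """For each strain: number and percentage of its present features that
    are also present in the host. Strains with zero features report
    (None, None)."""
    if fungal_table.presence is None or host_table.presence is None:
        raise ValueError("presence calls required")
    host_present = _presence_calls(host_table, HOST_TYPES)
    host_set = set(host_present.index[host_present]) & set(host_table.features.index)
    strains: dict[str, list[str]] = {}
    for s in fungal_table.samples_of_type({"fungal"}):
        strains.setdefault(fungal_table.meta.loc[s, "organism"], []).append(s)
    out = {}
    for strain in sorted(strains):
        pres = fungal_table.presence[strains[strain]].any(axis=1)
        strain_feats = set(pres.index[pres]) & set(fungal_table.features.index)
        if not strain_feats:
            out[strain] = (None, None)
            continue
        n_shared = len(strain_feats & host_set)
        out[strain] = (n_shared, percentage(n_shared, len(strain_feats), ndigits))
    return out


# --------------------------------------------------------------------------
# Fractionation enrichment
# --------------------------------------------------------------------------

def enrichment_stats(host_table: FeatureTable,
                     fungal_table: Optional[FeatureTable] = None,
                     n_general_total: Optional[int] = None) -> dict:
    """Crude-extract vs MPLC-fraction detection statistics.

    Reports the features present in the crude extract, in >= 1 fraction, the
    crude share of the host total (1 decimal), the fold gain of
    fractionation, and — when a fungal table is given — how many shared
    features would remain if the host had been profiled through the crude
    extract alone, as a percentage of the general total.
    """
    if host_table.presence is None:
        raise ValueError("presence calls required")
    crude_samples = host_table.samples_of_type({"host_crude"})
    fraction_samples = host_table.samples_of_type({"host_fraction"})
    host_ids = set(host_table.features.index)
    report: dict = {"n_host_total": len(host_ids)}
    in_fractions = host_table.presence[fraction_samples].any(axis=1)
    report["n_fractions"] = int((in_fractions & in_fractions.index.isin(host_ids)).sum())
    if not crude_samples:
        report["crude_available"] = False
        return report
    report["crude_available"] = True
    in_crude = host_table.presence[crude_samples].any(axis=1)
    crude_ids = set(in_crude.index[in_crude]) & host_ids
    report["n_crude"] = len(crude_ids)
    report["pct_crude"] = percentage(len(crude_ids), len(host_ids), 1) if host_ids else 0.0
    if report["n_crude"]:
        report["fold_enrichment"] = round_half_up(
            report["n_fractions"] / report["n_crude"], 1)
    if fungal_table is not None:
        fungal_present = _presence_calls(fungal_table, {"fungal"})
        fungal_set = set(fungal_present.index[fungal_present]) \
            & set(fungal_table.features.index)
        shared_crude = crude_ids & fungal_set
        report["n_shared_crude_only"] = len(shared_crude)
        total = n_general_total if n_general_total is not None \
            else len(host_ids | fungal_set)
        report["pct_shared_crude_only"] = percentage(len(shared_crude), total, 1)
    return report


# --------------------------------------------------------------------------
# Class distributions and sunbursts
# --------------------------------------------------------------------------

@dataclass
class ClassDistribution:
    level: str
    counts: dict[str, int]
    percents: dict[str, float]
    n_annotated: int
    n_total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.n_annotated:
            raise ValueError("class counts must sum to n_annotated")


def class_distribution(records: Mapping, feature_ids: Sequence[str],
                       level: str) -> ClassDistribution:
    """Distribution of consensus class labels at one ontology level over the
    annotated features of a subset. Unannotated features are excluded from
    the percentage denominator."""
    from .annotate import LEVEL_NAMES
    lvl = LEVEL_NAMES.index(level)
    counts: dict[str, int] = {}
    n_annotated = 0
    for fid in feature_ids:
        rec = records.get(fid)
        if rec is None:
            continue
        label = rec.consensus_triple[lvl]
        if label is None:
            continue
        n_annotated += 1
        counts[label] = counts.get(label, 0) + 1
    percents = {lab: percentage(c, n_annotated, 1) for lab, c in counts.items()} \
        if n_annotated else {}
    return ClassDistribution(level=level, counts=counts, percents=percents,
                             n_annotated=n_annotated, n_total=len(list(feature_ids)))


def sunburst_export(records: Mapping, feature_ids: Sequence[str], path=None) -> dict:
    """Nested pathway > superclass > class counts for sunburst plotting.

    Children counts sum exactly to their parent's count; features without a
    full consensus triple are skipped. Writes JSON when a path is given.
    """
    tree: dict = {}
    for fid in feature_ids:
        rec = records.get(fid)
        if rec is None:
            continue
        pw, sc, cl = rec.consensus_triple
        if pw is None or sc is None or cl is None:
            continue
        node = tree.setdefault(pw, {"count": 0, "children": {}})
        node["count"] += 1
        sub = node["children"].setdefault(sc, {"count": 0, "children": {}})
        sub["count"] += 1
        leaf = sub["children"].setdefault(cl, {"count": 0})
        leaf["count"] += 1
    for pw, node in tree.items():
        if node["count"] != sum(c["count"] for c in node["children"].values()):
            raise ValueError(f"hierarchy violation under {pw}")
    if path is not None:
        Path(path).write_text(json.dumps(tree, indent=1, sort_keys=True))
    return tree


# --------------------------------------------------------------------------
# Ground-truth recovery
# --------------------------------------------------------------------------

def match_features_to_truth(table: FeatureTable, truth,
                            ppm_tol: float = 10.0, rt_tol: float = 0.1) -> dict[str, str]:
    """Map aligned feature rows to ground-truth metabolites by protonated
    mass and retention time. Each feature maps to the closest metabolite
    within tolerance; unmatched features are absent from the mapping."""
    from .core import PROTON_MASS, ppm_diff
    mapping = {}
    mets = truth.metabolites + truth.contaminants + truth.media_metabolites
    for fid in table.features.index:
        mz = table.features.loc[fid, "mz"]
        rt = table.features.loc[fid, "rt"]
        best = None
        for m in mets:
            prec = m.monoisotopic_mass + PROTON_MASS
            dppm = ppm_diff(mz, prec)
            if dppm <= ppm_tol and abs(rt - m.rt_true) <= rt_tol:
                if best is None or dppm < best[0]:
                    best = (dppm, m.id)
        if best is not None:
            mapping[fid] = best[1]
    return mapping


def recovery_report(general: FeatureTable, fungal: FeatureTable,
                    host: FeatureTable, truth,
                    records: Optional[Mapping] = None) -> dict:
    """Precision/recall of the category calls against the ground truth.

    shared_host_strain is scored on the shared-feature call; host_only and
    strain_specific (plus multi_strain) on exclusive presence on the
    respective side. When annotation records are given, rank-1 structure
    accuracy over truth-mapped features is added. Undefined ratios (zero
    denominators) are reported as None.
    """
    mapping = match_features_to_truth(general, truth)
    effective = truth.effective_membership()
    _, _, shared_ids = shared_features(host, fungal)
    shared_ids = set(shared_ids)
    host_present = _presence_calls(general, HOST_TYPES) \
        & general.features.index.isin(host.features.index)
    fungal_present = _presence_calls(general, {"fungal"}) \
        & general.features.index.isin(fungal.features.index)

    called: dict[str, set[str]] = {c: set() for c in
                                   ("host_only", "strain_specific",
                                    "multi_strain", "shared_host_strain")}
    for fid, mid in mapping.items():
        if fid in shared_ids:
            called["shared_host_strain"].add(mid)
        elif host_present.get(fid, False) and not fungal_present.get(fid, False):
            called["host_only"].add(mid)
        elif fungal_present.get(fid, False) and not host_present.get(fid, False):
            called["strain_specific"].add(mid)
    # strain_specific vs multi_strain are both "fungal side only" calls; the
    # table alone cannot split them, so the truth's producer sets do
    fungal_only_called = called.pop("strain_specific")
    called["strain_specific"] = {m for m in fungal_only_called
                                 if effective.get(m) != "multi_strain"}
    called["multi_strain"] = {m for m in fungal_only_called
                              if effective.get(m) == "multi_strain"}

    report: dict = {}
    for cat in ("host_only", "strain_specific", "multi_strain", "shared_host_strain"):
        truth_ids = {mid for mid, c in effective.items() if c == cat}
        got = called[cat]
        tp = len(got & truth_ids)
        report[cat] = {
            "n_truth": len(truth_ids),
            "n_called": len(got),
            "precision": tp / len(got) if got else None,
            "recall": tp / len(truth_ids) if truth_ids else None,
        }
    if records is not None:
        hits = total = 0
        for fid, mid in mapping.items():
            rec = records.get(fid)
            if rec is None or mid.startswith(("C", "G")):
                continue
            total += 1
            if rec.candidates and rec.candidates[0].structure_id == mid:
                hits += 1
        report["rank1_annotation_accuracy"] = hits / total if total else None
    return report


def write_report_json(report, path) -> Path:
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
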