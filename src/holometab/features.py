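"""Feature-table construction and filtering for comparative metabolomics.

Reproduces the classic MZmine-style post-processing chain on per-injection
feature lists, followed by study-level table filtering:

    deduplicate -> group_isotopes -> require_ms2 -> align_join
    -> filter_blank -> filter_replicates -> normalize_average -> split_datasets

The replicate rule is the one used for comparative presence calls: a feature
is *retained* only if detected in all replicates of at least one biological
sample, and once retained it is called *present* in any other sample when
detected in at least two of that sample's replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ISOTOPE_SPACING, SampleFeature, Spectrum, ppm_diff

BLANK_TYPES = frozenset({"blank", "media_blank"})
BIOLOGICAL_TYPES = frozenset({"fungal", "host_fraction", "host_crude"})
HOST_TYPES = frozenset({"host_fraction", "host_crude"})
KNOWN_TYPES = BLANK_TYPES | BIOLOGICAL_TYPES | {"qc"}


@dataclass
class AlignParams:
    """Tolerances for deduplication, isotope grouping and join alignment.

    ppm tolerances are computed on the mean of the two masses; RT tolerances
    are absolute minutes. The join-aligner score weights mirror the original
    tool's m/z and RT weights.
    """

    dedup_ppm: float = 8.0
    dedup_rt_min: float = 0.03
    iso_ppm: float = 8.0
    iso_rt_min: float = 0.02
    iso_max_charge: int = 2
    align_ppm: float = 10.0
    align_rt_min: float = 0.04
    weight_mz: float = 10.0
    weight_rt: float = 10.0

    def __post_init__(self):
        for name, v in vars(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterParams:
    n_replicates_required: int = 3
    cooccurrence_min: int = 2
    blank_ratio: float = 0.1
    ms2_required: bool = True

    def __post_init__(self):
        if self.cooccurrence_min > self.n_replicates_required:
            raise ValueError("cooccurrence_min must be <= n_replicates_required")
        if self.blank_ratio < 0:
            raise ValueError("blank_ratio must be >= 0")


@dataclass
class FeatureTable:
    """Aligned features x injections, with metadata and presence calls.

    intensities/detection columns are a (sample_id, replicate) MultiIndex
    until normalize_average collapses them to one column per sample.
    presence (features x samples, boolean) is set by filter_replicates.
    """

    features: pd.DataFrame                       # index: row id; cols mz, rt
    intensities: pd.DataFrame                    # index: row id
    detection: pd.DataFrame                      # same shape, bool
    meta: pd.DataFrame                           # index: sample_id
    spectra: dict[str, Spectrum] = field(default_factory=dict)
    presence: Optional[pd.DataFrame] = None      # features x samples, bool
    members: dict[str, list[SampleFeature]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensity rows must match feature rows")
        if self.detection.shape != self.intensities.shape:
            raise ValueError("detection and intensity shapes differ")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def averaged(self) -> bool:
        return not isinstance(self.intensities.columns, pd.MultiIndex)

    @property
    def sample_ids(self) -> list[str]:
        if self.averaged:
            return list(self.intensities.columns)
        return list(self.intensities.columns.get_level_values(0).unique())

    def samples_of_type(self, types: Iterable[str]) -> list[str]:
        types = set(types)
        return [s for s in self.sample_ids
                if self.meta.loc[s, "sample_type"] in types]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            features=self.features.copy(), intensities=self.intensities.copy(),
            detection=self.detection.copy(), meta=self.meta.copy(),
            spectra=dict(self.spectra),
            presence=None if self.presence is None else self.presence.copy(),
            members={k: list(v) for k, v in self.members.items()})

    def subset_rows(self, row_ids: Sequence[str]) -> "FeatureTable":
        row_ids = list(row_ids)
        return FeatureTable(
            features=self.features.loc[row_ids], intensities=self.intensities.loc[row_ids],
            detection=self.detection.loc[row_ids], meta=self.meta,
            spectra={r: self.spectra[r] for r in row_ids if r in self.spectra},
            presence=None if self.presence is None else self.presence.loc[row_ids],
            members={r: self.members.get(r, []) for r in row_ids})


# --------------------------------------------------------------------------
# Per-injection list operations
# --------------------------------------------------------------------------

def _connected_groups(features: Sequence[SampleFeature], is_pair) -> list[list[int]]:
    """Connected components under a symmetric pairwise predicate."""
    n = len(features)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if is_pair(features[i], features[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def _keep_most_intense(features, groups):
    kept = []
    for g in groups:
        best = max(g, key=lambda i: (features[i].intensity, features[i].feature_id))
        kept.append(features[best])
    kept.sort(key=lambda f: f.feature_id)
    return kept


def deduplicate(features: Sequence[SampleFeature], params: AlignParams) -> list[SampleFeature]:
    """Collapse near-identical features from one injection.

    Features within both the m/z ppm and the RT tolerance are duplicates;
    duplicate groups are resolved transitively (maximal connected groups) and
    the most intense member survives.
    """

    def dup(a, b):
        return (ppm_diff(a.mz, b.mz) <= params.dedup_ppm
                and abs(a.rt - b.rt) <= params.dedup_rt_min)

    return _keep_most_intense(features, _connected_groups(features, dup))


def is_isotope_pair(a: SampleFeature, b: SampleFeature, params: AlignParams) -> bool:
    """True when two features look like isotopologues of one molecule:
    m/z spacing ~ n*1.003355/z for n in {1,2}, z in {1..max_charge}, within
    the ppm tolerance, and RT within tolerance."""
    if abs(a.rt - b.rt) > params.iso_rt_min:
        return False
    dmz = abs(a.mz - b.mz)
    tol = params.iso_ppm * 1e-6 * 0.5 * (a.mz + b.mz)
    for z in range(1, params.iso_max_charge + 1):
        for n in (1, 2):
            if abs(dmz - n * ISOTOPE_SPACING / z) <= tol:
                return True
    return False


def group_isotopes(features: Sequence[SampleFeature], params: AlignParams) -> list[SampleFeature]:
    """Merge isotopologue features; the most intense member (normally the
    monoisotopic peak) represents the group."""
    groups = _connected_groups(features, lambda a, b: is_isotope_pair(a, b, params))
    return _keep_most_intense(features, groups)


def require_ms2(features: Sequence[SampleFeature]) -> list[SampleFeature]:
    """Keep only features with an associated MS/MS scan."""
    return [f for f in features if f.spectrum is not None]


# --------------------------------------------------------------------------
# Join alignment
# --------------------------------------------------------------------------

def _align_score(f: SampleFeature, row_mz: float, row_rt: float, p: AlignParams):
    dppm = ppm_diff(f.mz, row_mz)
    drt = abs(f.rt - row_rt)
    if dppm > p.align_ppm or drt > p.align_rt_min:
        return None
    return p.weight_mz * (1 - dppm / p.align_ppm) + p.weight_rt * (1 - drt / p.align_rt_min)


def align_join(
    per_sample_lists: Mapping[tuple[str, int], Sequence[SampleFeature]],
    params: AlignParams,
    metadata: Optional[pd.DataFrame] = None,
) -> FeatureTable:
    """Join-align per-injection feature lists into one table.

    Lists are merged one at a time (in sorted injection order): each incoming
    feature is scored against every existing aligned row within both
    tolerances, score = w_mz*(1-|dppm|/tol) + w_rt*(1-|drt|/tol); candidate
    (feature, row) pairs are assigned greedily best-score-first, one-to-one
    per injection; leftovers open new rows. Row consensus m/z / RT is the
    running mean over members.
    """
    rows: list[dict] = []  # {"mz","rt","members"}
    for key in sorted(per_sample_lists):
        feats = sorted(per_sample_lists[key], key=lambda f: f.feature_id)
        cands = []
        for fi, f in enumerate(feats):
            for ri, row in enumerate(rows):
                s = _align_score(f, row["mz"], row["rt"], params)
                if s is not None:
                    cands.append((s, ri, fi))
        # greedy: best score first; ties by lower row index then feature id
        cands.sort(key=lambda t: (-t[0], t[1], feats[t[2]].feature_id))
        used_rows, used_feats = set(), set()
        for s, ri, fi in cands:
            if ri in used_rows or fi in used_feats:
                continue
            used_rows.add(ri)
            used_feats.add(fi)
            rows[ri]["members"].append(feats[fi])
            mem = rows[ri]["members"]
            rows[ri]["mz"] = float(np.mean([m.mz for m in mem]))
            rows[ri]["rt"] = float(np.mean([m.rt for m in mem]))
        for fi, f in enumerate(feats):
            if fi not in used_feats:
                rows.append({"mz": f.mz, "rt": f.rt, "members": [f]})

    rows.sort(key=lambda r: (r["mz"], r["rt"]))
    row_ids = [f"FT{i:05d}" for i in range(len(rows))]
    injections = sorted(per_sample_lists)
    cols = pd.MultiIndex.from_tuples(injections, names=["sample_id", "replicate"])
    inten = pd.DataFrame(0.0, index=row_ids, columns=cols)
    spectra: dict[str, Spectrum] = {}
    members: dict[str, list[SampleFeature]] = {}
    for rid, row in zip(row_ids, rows):
        members[rid] = row["members"]
        for m in row["members"]:
            inten.loc[rid, (m.sample_id, m.replicate)] = m.intensity
        with_spec = [m for m in row["members"] if m.spectrum is not None]
        if with_spec:
            rep = max(with_spec, key=lambda m: (m.intensity, m.feature_id))
            spectra[rid] = rep.spectrum
    feats_df = pd.DataFrame({"mz": [r["mz"] for r in rows],
                             "rt": [r["rt"] for r in rows]}, index=row_ids)
    if metadata is not None:
        meta = metadata.drop_duplicates("sample_id").set_index("sample_id")[
            ["sample_type", "organism", "taxon_id"]]
    else:
        meta = pd.DataFrame(index=pd.Index([s for s, _ in injections], name="sample_id"))
    return FeatureTable(features=feats_df, intensities=inten,
                        detection=inten > 0, meta=meta, spectra=spectra,
                        members=members)


# --------------------------------------------------------------------------
# Table-level filters
# --------------------------------------------------------------------------

def _check_types(table: FeatureTable):
    types = set(table.meta.loc[table.sample_ids, "sample_type"])
    unknown = types - KNOWN_TYPES
    if unknown:
        raise ValueError(f"unknown sample_type values: {sorted(unknown)}")


def filter_blank(table: FeatureTable, params: FilterParams) -> FeatureTable:
    """Discard features attributable to solvent or culture-medium background.

    A row is removed when its mean intensity over all blank and media-blank
    injections exceeds blank_ratio times its best biological per-sample mean.
    Blank columns are dropped from the output.
    """
    _check_types(table)
    blanks = table.samples_of_type(BLANK_TYPES)
    if not blanks:
        warnings.warn("no blank samples in table; blank filter is a no-op")
        return table.copy()
    bio = table.samples_of_type(BIOLOGICAL_TYPES)
    if table.averaged:
        blank_mean = table.intensities[blanks].mean(axis=1)
        bio_best = table.intensities[bio].max(axis=1)
    else:
        blank_mean = table.intensities.loc[:, blanks].mean(axis=1)
        per_sample_mean = table.intensities.loc[:, bio].T.groupby(level=0).mean().T
        bio_best = per_sample_mean.max(axis=1)
    keep = ~(blank_mean > params.blank_ratio * bio_best)
    out = table.subset_rows(table.features.index[keep])
    keep_cols = [c for c in out.intensities.columns
                 if (c if out.averaged else c[0]) not in set(blanks)]
    out.intensities = out.intensities[keep_cols]
    out.detection = out.detection[keep_cols]
    return out


def filter_replicates(table: FeatureTable, params: FilterParams) -> FeatureTable:
    """Apply the replicate retention and co-occurrence rules.

    Retention: detected in all n_replicates_required replicates of at least
    one biological sample. Presence: detected in >= cooccurrence_min
    replicates of a sample. Intensities of samples below the co-occurrence
    threshold are zeroed.
    """
    if table.averaged:
        raise ValueError("filter_replicates requires replicate-level columns")
    _check_types(table)
    bio = table.samples_of_type(BIOLOGICAL_TYPES)
    counts = table.intensities.columns.to_frame(index=False).groupby("sample_id").size()
    bad = [s for s in bio if counts.get(s, 0) != params.n_replicates_required]
    if bad:
        raise ValueError(
            f"samples without exactly {params.n_replicates_required} replicates: {bad}")
    det_by_sample = table.detection.T.groupby(level=0).sum().T  # features x samples
    retained = (det_by_sample[bio] >= params.n_replicates_required).any(axis=1)
    out = table.subset_rows(table.features.index[retained])
    presence = det_by_sample.loc[out.features.index, out.sample_ids] >= params.cooccurrence_min
    # zero out sub-threshold detections
    for s in out.sample_ids:
        absent = ~presence[s]
        cols = [c for c in out.intensities.columns if c[0] == s]
        out.intensities.loc[absent, cols] = 0.0
        out.detection.loc[absent, cols] = False
    out.presence = presence
    return out


def normalize_average(table: FeatureTable) -> FeatureTable:
    """Average replicates to one column per sample, then scale each row so
    its across-sample intensity sum is 1."""
    if table.averaged:
        means = table.intensities.copy()
    else:
        means = table.intensities.T.groupby(level=0).mean().T
        means = means[sorted(means.columns, key=list(
            table.intensities.columns.get_level_values(0).unique()).index)]
    row_sums = means.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        raise ValueError(f"cannot normalize all-zero rows: {list(means.index[zero])}")
    norm = means.div(row_sums, axis=0)
    out = table.copy()
    out.intensities = norm
    out.detection = norm > 0
    if table.presence is not None:
        out.presence = table.presence.loc[norm.index, norm.columns]
    return out


def split_datasets(table: FeatureTable):
    """Split into (fungal, host, general) tables by sample origin.

    A row goes to the fungal table when present in >= 1 fungal sample and to
    the host table when present in >= 1 leaf sample (fraction or crude); the
    general table is their union. Row ids are preserved so the overlap
    between the three is directly computable.
    """
    _check_types(table)
    if table.presence is None:
        raise ValueError("presence calls required; run filter_replicates first")
    fungal_samples = table.samples_of_type({"fungal"})
    host_samples = table.samples_of_type(HOST_TYPES)
    in_fungal = table.presence[fungal_samples].any(axis=1)
    in_host = table.presence[host_samples].any(axis=1)
    fungal = table.subset_rows(table.features.index[in_fungal])
    host = table.subset_rows(table.features.index[in_host])
    general = table.subset_rows(table.features.index[in_fungal | in_host])
    return fungal, host, general


# --------------------------------------------------------------------------
# Pipeline convenience + CSV export
# --------------------------------------------------------------------------

def process_dataset(
    per_sample_lists: Mapping[tuple[str, int], Sequence[SampleFeature]],
    metadata: pd.DataFrame,
    align: Optional[AlignParams] = None,
    filt: Optional[FilterParams] = None,
):
    """Full chain from raw per-injection lists to the three averaged tables.

    Returns (general, fungal, host) FeatureTables.
    """
    align = align or AlignParams()
    filt = filt or FilterParams()
    cleaned = {}
    for key, feats in per_sample_lists.items():
        fl = deduplicate(feats, align)
        fl = group_isotopes(fl, align)
        if filt.ms2_required:
            fl = require_ms2(fl)
        cleaned[key] = fl
    table = align_join(cleaned, align, metadata)
    table = filter_blank(table, filt)
    table = filter_replicates(table, filt)
    table = normalize_average(table)
    fungal, host, general = split_datasets(table)
    return general, fungal, host


def write_table_csv(table: FeatureTable, directory, name: str) -> dict:
    """Write the intensity table (rows: id, mz, rt; columns: samples) and a
    companion detection/presence CSV."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    inten = table.intensities.copy()
    if not table.averaged:
        inten.columns = [f"{s}_r{r}" for s, r in inten.columns]
    quant = pd.concat([table.features, inten], axis=1)
    qpath = directory / f"{name}_quant.csv"
    quant.to_csv(qpath, index_label="feature_id")
    paths = {"quant": qpath}
    if table.presence is not None:
        ppath = directory / f"{name}_presence.csv"
        table.presence.to_csv(ppath, index_label="feature_id")
        paths["presence"] = ppath
    return paths
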