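"""Seeded synthetic host-endophyte metabolomics studies.

Emulates the structure of a holobiont profiling campaign: a set of fungal
endophyte strains cultured and extracted individually, one host leaf extract
fractionated into preparative (MPLC) fractions plus the unfractionated crude
extract, all profiled by LC-MS/MS in analytical triplicates alongside solvent
blanks and uninoculated-media blanks.

Every generated object carries the ground truth (which organism produces
which metabolite, and in which category: host-only, strain-specific,
multi-strain, or shared between host and strains) so that downstream
filtering, networking, annotation and overlap statistics can be scored
against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .core import PROTON_MASS, ISOTOPE_SPACING, SampleFeature, Spectrum

HOST_ID = "host"
SOLVENT_ID = "__solvent__"
MEDIA_ID = "__media__"

LEVELS = ("pathway", "superclass", "class")

_SYLLABLES = [
    "ter", "pen", "oid", "fla", "von", "alk", "lip", "phen", "gly", "cos",
    "ste", "rol", "qui", "non", "lac", "ton", "cum", "arin", "sac", "rid",
]


# --------------------------------------------------------------------------
# Chemical-class ontology (three levels: pathway > superclass > class)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassOntology:
    """A three-level chemical ontology: pathway, superclass, class.

    ``parent`` maps each label to its parent label on the level above
    (pathways have no entry).
    """

    levels: tuple[str, str, str]
    nodes: dict[str, tuple[str, ...]]       # level name -> labels
    parent: dict[str, str]                  # label -> parent label

    def __post_init__(self):
        for lo, hi in zip(self.levels[1:], self.levels[:-1]):
            for label in self.nodes[lo]:
                p = self.parent.get(label)
                if p is None or p not in self.nodes[hi]:
                    raise ValueError(f"label {label!r} lacks a parent on level {hi!r}")
        seen = set()
        for level in self.levels:
            for label in self.nodes[level]:
                if label in seen:
                    raise ValueError(f"duplicate label {label!r}")
                seen.add(label)

    def triple_for_class(self, class_label: str) -> tuple[str, str, str]:
        """Resolve (pathway, superclass, class) from a class-level label."""
        sc = self.parent[class_label]
        pw = self.parent[sc]
        return (pw, sc, class_label)

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "nodes": {k: list(v) for k, v in self.nodes.items()},
            "parent": dict(self.parent),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassOntology":
        return cls(
            levels=tuple(d["levels"]),
            nodes={k: tuple(v) for k, v in d["nodes"].items()},
            parent=dict(d["parent"]),
        )


def _label(rng: np.random.Generator, prefix: str, taken: set[str]) -> str:
    while True:
        name = prefix + "-" + "".join(rng.choice(_SYLLABLES, size=3))
        if name not in taken:
            taken.add(name)
            return name


def generate_ontology(n_pathways: int, branching: int, seed: int) -> ClassOntology:
    """Build a random but seed-deterministic 3-level class ontology.

    Each pathway has `branching` superclasses and each superclass `branching`
    classes, so the level sizes are n, n*b, n*b^2.
    """
    if n_pathways < 1 or branching < 1:
        raise ValueError("n_pathways and branching must be >= 1")
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    pathways, supers, classes = [], [], []
    parent: dict[str, str] = {}
    for _ in range(n_pathways):
        pw = _label(rng, "pw", taken)
        pathways.append(pw)
        for _ in range(branching):
            sc = _label(rng, "sc", taken)
            supers.append(sc)
            parent[sc] = pw
            for _ in range(branching):
                cl = _label(rng, "cl", taken)
                classes.append(cl)
                parent[cl] = sc
    return ClassOntology(
        levels=LEVELS,
        nodes={"pathway": tuple(pathways), "superclass": tuple(supers),
               "class": tuple(classes)},
        parent=parent,
    )


# --------------------------------------------------------------------------
# Study design and metabolites
# --------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Stochastic distortions applied when rendering features.

    intensity_sigma is the sigma of a multiplicative lognormal on abundance;
    m/z and RT jitters are uniform within the stated bound; dropout is the
    per-(metabolite, injection) probability of a missed detection; decoy
    peaks are low-intensity spurious fragments added to each MS/MS spectrum.
    """

    intensity_sigma: float = 0.3
    mz_jitter_ppm: float = 2.0
    rt_jitter_min: float = 0.005
    dropout: float = 0.1
    n_decoy_peaks: int = 3

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        for v in (self.intensity_sigma, self.mz_jitter_ppm, self.rt_jitter_min):
            if v < 0:
                raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(intensity_sigma=0.0, mz_jitter_ppm=0.0, rt_jitter_min=0.0,
                   dropout=0.0, n_decoy_peaks=0)


def default_strains(n: int = 15) -> list[tuple[str, str]]:
    return [(f"A{i}", f"tax_A{i}") for i in range(1, n + 1)]


@dataclass
class StudyDesign:
    """Layout of a synthetic profiling campaign.

    Defaults mirror the emulated study: 15 endophyte strains each yielding
    2 extracts, 47 host fractions plus a crude extract, analytical
    triplicates, 2 solvent and 2 media blanks (each also injected in
    triplicate), 0-8 min RT domain and a 130-1950 Da mass window.
    """

    strains: list[tuple[str, str]] = field(default_factory=default_strains)
    n_fractions: int = 47
    n_replicates: int = 3
    include_crude: bool = True
    n_extracts_per_strain: int = 2
    n_solvent_blanks: int = 2
    n_media_blanks: int = 2
    noise: NoiseModel = field(default_factory=NoiseModel)
    lod: float = 4e5
    seed: int = 0
    mass_window: tuple[float, float] = (130.0, 1950.0)
    rt_window: tuple[float, float] = (0.2, 7.8)
    crude_dilution: float = 0.05
    isotope_ratio: float = 0.25
    n_contaminants: int = 4
    n_media_metabolites: int = 4
    host_taxon: str = "tax_host"

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not self.strains:
            raise ValueError("at least one strain required")

    def sample_plan(self) -> list[tuple[str, str, str, str]]:
        """(sample_id, sample_type, organism, taxon_id) for every sample."""
        plan = []
        for sid, tax in self.strains:
            for e in range(1, self.n_extracts_per_strain + 1):
                plan.append((f"{sid}_E{e}", "fungal", sid, tax))
        for i in range(1, self.n_fractions + 1):
            plan.append((f"F{i:02d}", "host_fraction", HOST_ID, self.host_taxon))
        if self.include_crude:
            plan.append(("CRUDE", "host_crude", HOST_ID, self.host_taxon))
        for i in range(1, self.n_solvent_blanks + 1):
            plan.append((f"BLK{i}", "blank", "", ""))
        for i in range(1, self.n_media_blanks + 1):
            plan.append((f"MEDIA{i}", "media_blank", "", ""))
        return plan

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strains"] = [list(s) for s in self.strains]
        d["mass_window"] = list(self.mass_window)
        d["rt_window"] = list(self.rt_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        d["strains"] = [tuple(s) for s in d["strains"]]
        d["mass_window"] = tuple(d["mass_window"])
        d["rt_window"] = tuple(d["rt_window"])
        d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)


@dataclass(frozen=True)
class Metabolite:
    id: str
    monoisotopic_mass: float
    rt_true: float
    class_triple: tuple[str, str, str]
    producers: frozenset[str]
    fragment_template: tuple[tuple[float, float], ...]  # (mz, rel intensity <= 1)
    base_abundance: float

    def __post_init__(self):
        if not self.producers:
            raise ValueError(f"metabolite {self.id} has no producers")
        if self.fragment_template:
            rels = [r for _, r in self.fragment_template]
            if abs(max(rels) - 1.0) > 1e-9:
                raise ValueError(f"metabolite {self.id}: max relative intensity must be 1")
            # fragments must sit below the lightest plausible adduct precursor
            if max(m for m, _ in self.fragment_template) >= self.monoisotopic_mass - 18.0:
                raise ValueError(f"metabolite {self.id}: fragment above precursor window")


CATEGORIES = ("host_only", "strain_specific", "multi_strain", "shared_host_strain")


@dataclass
class GroundTruthMetabolome:
    """The recovery oracle: metabolites, who makes them, how the host's are
    distributed over the MPLC fractions, plus blank/media contaminants."""

    metabolites: list[Metabolite]
    design: StudyDesign
    membership: dict[str, str]                 # metabolite id -> category
    fraction_profile: dict[str, np.ndarray]    # host metabolite id -> per-fraction weights
    contaminants: list[Metabolite] = field(default_factory=list)
    media_metabolites: list[Metabolite] = field(default_factory=list)

    def __post_init__(self):
        for m in self.metabolites:
            cat = self.membership.get(m.id)
            has_host = HOST_ID in m.producers
            strains = m.producers - {HOST_ID}
            ok = {
                "host_only": has_host and not strains,
                "strain_specific": not has_host and len(strains) == 1,
                "multi_strain": not has_host and len(strains) >= 2,
                "shared_host_strain": has_host and len(strains) >= 1,
            }.get(cat, False)
            if not ok:
                raise ValueError(f"membership {cat!r} inconsistent with producers of {m.id}")
            if has_host:
                prof = self.fraction_profile[m.id]
                if abs(float(prof.sum()) - 1.0) > 1e-9:
                    raise ValueError(f"fraction profile of {m.id} does not sum to 1")

    def by_category(self, category: str) -> list[Metabolite]:
        return [m for m in self.metabolites if self.membership[m.id] == category]

    def effective_membership(self) -> dict[str, str]:
        """Membership restricted to what is detectable at the design's limit
        of detection under noiseless rendering.

        A metabolite whose host-side abundance never clears the LOD in any
        fraction or the crude extract is not recoverable on the host side by
        any pipeline, so its effective category drops that side (and
        likewise for strains). Metabolites detectable nowhere are omitted.
        """
        d = self.design
        out: dict[str, str] = {}
        for m in self.metabolites:
            strains_det = {s for s in m.producers - {HOST_ID}
                           if m.base_abundance >= d.lod}
            host_det = False
            if HOST_ID in m.producers:
                prof = self.fraction_profile[m.id]
                host_det = bool((m.base_abundance * prof >= d.lod).any())
                if d.include_crude:
                    host_det = host_det or (m.base_abundance * d.crude_dilution >= d.lod)
            if host_det and strains_det:
                out[m.id] = "shared_host_strain"
            elif host_det:
                out[m.id] = "host_only"
            elif len(strains_det) == 1:
                out[m.id] = "strain_specific"
            elif len(strains_det) >= 2:
                out[m.id] = "multi_strain"
        return out


def _draw_mass(rng, window, taken_masses, min_sep=0.05):
    lo, hi = window
    for _ in range(10000):
        m = float(rng.uniform(lo, hi))
        if all(abs(m - t) >= min_sep for t in taken_masses):
            taken_masses.append(m)
            return m
    raise RuntimeError("could not place metabolite mass with required separation")


def _make_fragments(rng, mass, n_lo=8, n_hi=14):
    n = int(rng.integers(n_lo, n_hi + 1))
    hi = mass - 20.0
    mzs = np.sort(rng.uniform(50.0, hi, size=n))
    # enforce >=0.5 Da spacing so peaks are unambiguous at the Da-level tolerances
    keep = [0]
    for i in range(1, n):
        if mzs[i] - mzs[keep[-1]] >= 0.5:
            keep.append(i)
    mzs = mzs[keep]
    rel = rng.uniform(0.05, 1.0, size=mzs.size)
    rel[int(rng.integers(0, mzs.size))] = 1.0
    rel = rel / rel.max()
    return tuple((float(m), float(r)) for m, r in zip(mzs, rel))


def _make_metabolite(rng, mid, producers, ontology, design, taken_masses) -> Metabolite:
    mass = _draw_mass(rng, design.mass_window, taken_masses)
    rt = float(rng.uniform(*design.rt_window))
    cl = str(rng.choice(ontology.nodes["class"]))
    abundance = float(rng.lognormal(mean=np.log(5e6), sigma=0.8))
    return Metabolite(
        id=mid,
        monoisotopic_mass=mass,
        rt_true=rt,
        class_triple=ontology.triple_for_class(cl),
        producers=frozenset(producers),
        fragment_template=_make_fragments(rng, mass),
        base_abundance=abundance,
    )


def generate_metabolome(
    ontology: ClassOntology,
    design: StudyDesign,
    counts: Mapping[str, int],
    seed: int,
) -> GroundTruthMetabolome:
    """Draw a ground-truth metabolome with the requested category counts.

    Categories: host_only (leaf only), strain_specific (one endophyte),
    multi_strain (>=2 endophytes, not the host), shared_host_strain (the
    host and >=1 endophyte — the category the overlap statistics target).
    """
    if not ontology.nodes["class"]:
        raise ValueError("empty ontology")
    bad = set(counts) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    strain_ids = [s for s, _ in design.strains]
    taken: list[float] = []
    metabolites: list[Metabolite] = []
    membership: dict[str, str] = {}
    k = 0

    def producers_for(cat: str, i: int) -> set[str]:
        if cat == "host_only":
            return {HOST_ID}
        if cat == "strain_specific":
            return {strain_ids[i % len(strain_ids)]}
        if cat == "multi_strain":
            n = int(rng.integers(2, min(4, len(strain_ids)) + 1))
            return set(rng.choice(strain_ids, size=n, replace=False))
        n = int(rng.integers(1, min(2, len(strain_ids)) + 1))
        return {HOST_ID, *rng.choice(strain_ids, size=n, replace=False)}

    for cat in CATEGORIES:
        for i in range(int(counts.get(cat, 0))):
            mid = f"M{k:04d}"
            k += 1
            m = _make_metabolite(rng, mid, producers_for(cat, i), ontology, design, taken)
            metabolites.append(m)
            membership[mid] = cat

    fraction_profile: dict[str, np.ndarray] = {}
    for m in metabolites:
        if HOST_ID in m.producers:
            center = rng.uniform(0, design.n_fractions - 1)
            width = rng.uniform(0.8, 2.5)
            idx = np.arange(design.n_fractions)
            w = np.exp(-0.5 * ((idx - center) / width) ** 2)
            fraction_profile[m.id] = w / w.sum()

    contaminants = [
        _make_metabolite(rng, f"C{j:02d}", {SOLVENT_ID}, ontology, design, taken)
        for j in range(design.n_contaminants)
    ]
    media = [
        _make_metabolite(rng, f"G{j:02d}", {MEDIA_ID}, ontology, design, taken)
        for j in range(design.n_media_metabolites)
    ]
    return GroundTruthMetabolome(
        metabolites=metabolites,
        design=design,
        membership=membership,
        fraction_profile=fraction_profile,
        contaminants=contaminants,
        media_metabolites=media,
    )


# --------------------------------------------------------------------------
# Rendering samples
# --------------------------------------------------------------------------

def _abundance_in_sample(truth: GroundTruthMetabolome, m: Metabolite,
                         sample_type: str, organism: str, sample_id: str) -> float:
    d = truth.design
    if m.producers == frozenset({SOLVENT_ID}):
        return m.base_abundance  # solvent contaminant: everywhere
    if m.producers == frozenset({MEDIA_ID}):
        # media background: in media blanks and every fungal culture extract
        return m.base_abundance if sample_type in ("media_blank", "fungal") else 0.0
    if sample_type in ("blank", "media_blank"):
        return 0.0
    if sample_type == "fungal":
        return m.base_abundance if organism in m.producers else 0.0
    if HOST_ID not in m.producers:
        return 0.0
    if sample_type == "host_fraction":
        i = int(sample_id[1:]) - 1
        return m.base_abundance * float(truth.fraction_profile[m.id][i])
    if sample_type == "host_crude":
        return m.base_abundance * d.crude_dilution
    raise ValueError(f"unknown sample type {sample_type!r}")


def simulate_samples(truth: GroundTruthMetabolome):
    """Render per-injection feature lists from the ground truth.

    Returns (features, metadata) where features maps (sample_id, replicate)
    to a list of SampleFeature and metadata is a pandas DataFrame with one
    row per injection (sample_id, replicate, sample_type, organism,
    taxon_id).

    Each detected metabolite contributes a protonated-molecule feature
    (m/z = mass + 1.007276, jittered) carrying its MS/MS spectrum, and an
    M+1 isotope feature (no MS/MS) whenever the isotope intensity clears the
    limit of detection. Detection requires realized intensity >= lod and
    survival of the dropout draw.
    """
    import pandas as pd

    d = truth.design
    rng = np.random.default_rng(d.seed)
    nz = d.noise
    plan = d.sample_plan()
    all_mets = truth.metabolites + truth.contaminants + truth.media_metabolites

    features: dict[tuple[str, int], list[SampleFeature]] = {}
    meta_rows = []
    for sample_id, stype, organism, taxon in plan:
        for rep in range(1, d.n_replicates + 1):
            feats: list[SampleFeature] = []
            k = 0
            for m in all_mets:
                ab = _abundance_in_sample(truth, m, stype, organism, sample_id)
                if ab <= 0:
                    continue
                inten = ab * float(np.exp(rng.normal(0.0, nz.intensity_sigma))) \
                    if nz.intensity_sigma > 0 else ab
                dropped = nz.dropout > 0 and rng.random() < nz.dropout
                if inten < d.lod or dropped:
                    continue
                prec = m.monoisotopic_mass + PROTON_MASS
                mz = prec * (1.0 + rng.uniform(-nz.mz_jitter_ppm, nz.mz_jitter_ppm) * 1e-6) \
                    if nz.mz_jitter_ppm > 0 else prec
                rt = m.rt_true + (rng.uniform(-nz.rt_jitter_min, nz.rt_jitter_min)
                                  if nz.rt_jitter_min > 0 else 0.0)
                rt = max(rt, 0.0)
                fr_mz = np.array([p for p, _ in m.fragment_template])
                fr_it = np.array([r for _, r in m.fragment_template]) * inten
                if nz.n_decoy_peaks > 0:
                    dmz = rng.uniform(50.0, prec - 10.0, size=nz.n_decoy_peaks)
                    dit = rng.uniform(0.0, 0.05, size=nz.n_decoy_peaks) * fr_it.max()
                    fr_mz = np.concatenate([fr_mz, dmz])
                    fr_it = np.concatenate([fr_it, dit])
                spec = Spectrum(precursor_mz=mz, rt=rt, mz=fr_mz, intensities=fr_it)
                feats.append(SampleFeature(
                    feature_id=f"{sample_id}_R{rep}_{k:04d}", sample_id=sample_id,
                    replicate=rep, mz=mz, rt=rt, intensity=inten, spectrum=spec))
                k += 1
                iso_int = inten * d.isotope_ratio
                if iso_int >= d.lod and d.isotope_ratio > 0:
                    feats.append(SampleFeature(
                        feature_id=f"{sample_id}_R{rep}_{k:04d}", sample_id=sample_id,
                        replicate=rep, mz=mz + ISOTOPE_SPACING, rt=rt,
                        intensity=iso_int, spectrum=None))
                    k += 1
            features[(sample_id, rep)] = feats
            meta_rows.append({"sample_id": sample_id, "replicate": rep,
                              "sample_type": stype, "organism": organism,
                              "taxon_id": taxon})
    metadata = pd.DataFrame(meta_rows)
    return features, metadata


# --------------------------------------------------------------------------
# Fixture I/O (MGF + TSV + JSON)
# --------------------------------------------------------------------------

def write_fixture(truth: GroundTruthMetabolome, features, metadata, directory) -> dict:
    """Write a complete study to disk: one MGF with all features (GNPS-style
    keys plus SAMPLE_ID/REPLICATE), the sample-metadata TSV and the
    ground-truth JSON. Returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mgf_path = directory / "dataset.mgf"
    entries = []
    for (sample_id, rep) in sorted(features):
        for f in features[(sample_id, rep)]:
            spec = f.spectrum
            entries.append({
                "m/z array": spec.mz if spec is not None else np.array([]),
                "intensity array": spec.intensities if spec is not None else np.array([]),
                "params": {
                    "FEATURE_ID": f.feature_id,
                    "PEPMASS": f"{f.mz!r} {f.intensity!r}",
                    "RTINSECONDS": f.rt * 60.0,
                    "CHARGE": "1+",
                    "SAMPLE_ID": f.sample_id,
                    "REPLICATE": f.replicate,
                },
            })
    with open(mgf_path, "w") as fh:
        _mgf.write(entries, fh)

    meta_path = directory / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False)

    truth_path = directory / "ground_truth.json"
    payload = {
        "design": truth.design.to_dict(),
        "membership": truth.membership,
        "fraction_profile": {k: v.tolist() for k, v in truth.fraction_profile.items()},
        "metabolites": [_met_dict(m) for m in truth.metabolites],
        "contaminants": [_met_dict(m) for m in truth.contaminants],
        "media_metabolites": [_met_dict(m) for m in truth.media_metabolites],
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"mgf": mgf_path, "metadata": meta_path, "ground_truth": truth_path}


def _met_dict(m: Metabolite) -> dict:
    return {
        "id": m.id,
        "monoisotopic_mass": m.monoisotopic_mass,
        "rt_true": m.rt_true,
        "class_triple": list(m.class_triple),
        "producers": sorted(m.producers),
        "fragment_template": [list(p) for p in m.fragment_template],
        "base_abundance": m.base_abundance,
    }


def _met_from_dict(d: dict) -> Metabolite:
    return Metabolite(
        id=d["id"], monoisotopic_mass=d["monoisotopic_mass"], rt_true=d["rt_true"],
        class_triple=tuple(d["class_triple"]), producers=frozenset(d["producers"]),
        fragment_template=tuple(tuple(p) for p in d["fragment_template"]),
        base_abundance=d["base_abundance"])


def read_ground_truth(path) -> GroundTruthMetabolome:
    d = json.loads(Path(path).read_text())
    return GroundTruthMetabolome(
        metabolites=[_met_from_dict(x) for x in d["metabolites"]],
        design=StudyDesign.from_dict(d["design"]),
        membership=d["membership"],
        fraction_profile={k: np.asarray(v) for k, v in d["fraction_profile"].items()},
        contaminants=[_met_from_dict(x) for x in d["contaminants"]],
        media_metabolites=[_met_from_dict(x) for x in d["media_metabolites"]],
    )


def read_metadata(path):
    import pandas as pd
    return pd.read_csv(path, sep="\t", dtype={"replicate": int}, keep_default_na=False)


def read_mgf_features(path) -> dict[tuple[str, int], list[SampleFeature]]:
    """Read an MGF written by write_fixture (or one MGF per sample, in which
    case SAMPLE_ID defaults to the file stem and REPLICATE to 1)."""
    path = Path(path)
    features: dict[tuple[str, int], list[SampleFeature]] = {}
    with _mgf.MGF(str(path)) as reader:
        it = iter(reader)
        i = -1
        while True:
            i += 1
            try:
                entry = next(it)
            except StopIteration:
                break
            except Exception as exc:
                raise ValueError(f"malformed MGF entry {i} in {path}: {exc}") from exc
            p = entry["params"]
            try:
                pep = p["pepmass"]
                mz = float(pep[0])
                inten = float(pep[1]) if len(pep) > 1 and pep[1] is not None else 0.0
                rt = float(p.get("rtinseconds", 0.0)) / 60.0
                fid = str(p.get("feature_id", f"{path.stem}_{i}"))
                sample_id = str(p.get("sample_id", path.stem))
                rep = int(p.get("replicate", 1))
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed MGF entry {i} in {path}: {exc}") from exc
            peaks_mz = np.asarray(entry.get("m/z array", []), dtype=float)
            peaks_it = np.asarray(entry.get("intensity array", []), dtype=float)
            spec = None
            if peaks_mz.size:
                spec = Spectrum(precursor_mz=mz, rt=rt, mz=peaks_mz, intensities=peaks_it)
            features.setdefault((sample_id, rep), []).append(SampleFeature(
                feature_id=fid, sample_id=sample_id, replicate=rep,
                mz=mz, rt=rt, intensity=inten, spectrum=spec))
    return features


# --------------------------------------------------------------------------
# Derived study resources: taxonomy and spectral library
# --------------------------------------------------------------------------

def make_taxonomy(design: StudyDesign):
    """Build the study taxonomy: every strain as a fungal species (grouped
    pairwise into genera, then families, orders, classes under one phylum),
    the host as a plant species on a disjoint lineage. The two kingdoms meet
    only at the root, so host-fungus distance is maximal."""
    from .annotate import TaxonomyTree, RANKS

    nodes: dict[str, tuple[str, str, str | None]] = {"root": ("root", "root", None)}

    def chain(prefix: str, kingdom_name: str):
        prev = "root"
        ids = {}
        for rank in reversed(RANKS[1:]):  # kingdom down to genus
            nid = f"{prefix}_{rank}"
            nodes[nid] = (f"{kingdom_name}-{rank}", rank, prev)
            prev = nid
            ids[rank] = nid
        return ids

    plant = chain("plantae", "Plantae")
    nodes[design.host_taxon] = ("host-species", "species", plant["genus"])

    # fungal side: group strains 2-per-genus, genera 2-per-family, etc.
    prev = "root"
    for rank in ("kingdom", "phylum", "class"):
        nid = f"fungi_{rank}"
        nodes[nid] = (f"Fungi-{rank}", rank, prev)
        prev = nid
    strain_taxa = [t for _, t in design.strains]
    n = len(strain_taxa)
    n_genera = (n + 1) // 2
    n_families = (n_genera + 1) // 2
    n_orders = (n_families + 1) // 2
    for o in range(n_orders):
        nodes[f"fungi_order{o}"] = (f"order-{o}", "order", "fungi_class")
    for f in range(n_families):
        nodes[f"fungi_family{f}"] = (f"family-{f}", "family", f"fungi_order{f // 2}")
    for g in range(n_genera):
        nodes[f"fungi_genus{g}"] = (f"genus-{g}", "genus", f"fungi_family{g // 2}")
    for i, t in enumerate(strain_taxa):
        nodes[t] = (f"strain-species-{i}", "species", f"fungi_genus{i // 2}")
    return TaxonomyTree(nodes=nodes)


def make_library(truth: GroundTruthMetabolome, complete: bool = True):
    """Build the reference spectral library from the ground truth: one entry
    per metabolite whose reference spectrum is the clean fragment template
    and whose source taxa are the producers' species-level taxa."""
    from .annotate import LibraryEntry

    design = truth.design
    tax_of = {s: t for s, t in design.strains}
    tax_of[HOST_ID] = design.host_taxon
    entries = []
    for m in truth.metabolites:
        taxa = {tax_of[p] for p in m.producers if p in tax_of}
        mz = np.array([p for p, _ in m.fragment_template])
        it = np.array([r for _, r in m.fragment_template])
        spec = Spectrum(precursor_mz=m.monoisotopic_mass + PROTON_MASS,
                        rt=m.rt_true, mz=mz, intensities=it)
        entries.append(LibraryEntry(
            structure_id=m.id, name=f"synthetic-{m.id}",
            monoisotopic_mass=m.monoisotopic_mass, spectrum=spec,
            class_triple=m.class_triple, source_taxa=frozenset(taxa)))
    return entries
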