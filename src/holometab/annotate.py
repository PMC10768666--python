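"""Metabolite annotation with taxonomic and network-topology re-ranking.

The cascade mirrors current natural-products annotation practice:

1. MS1 adduct matching restricted to compounds reported in the sample's
   taxonomic family.
2. MS2 spectral-library search (modified cosine) yielding up to 50 candidate
   structures per feature.
3. Taxonomically informed re-ranking: a candidate whose reported biological
   source is close to the analyzed organism gets a score bonus inversely
   proportional to the taxonomic distance.
4. Consensus chemical class per network node (pathway / superclass / class),
   pooled over the node and its direct neighbors, with a small bonus for
   candidates matching the consensus; the top three candidates are retained.
5. Identity matching against a standards library (m/z 20 ppm, cosine >= 0.8)
   gives the "confirmed" annotation tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Spectrum, ppm_diff
from .msnet import MolecularNetwork, SpectralMatch, cosine_direct, modified_cosine

RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")
MAX_DISTANCE = len(RANKS)  # no common ancestor below the root

DEFAULT_ADDUCTS: tuple[tuple[str, float], ...] = (
    ("[M+H]+", 1.007276),
    ("[M+Na]+", 22.989218),
    ("[M+NH4]+", 18.033823),
    ("[M+K]+", 38.963158),
    ("[M+H-H2O]+", -17.002740),
)


@dataclass
class AnnotationParams:
    parent_tol_da: float = 0.01
    msms_tol_da: float = 0.01
    min_cosine: float = 0.2
    min_peaks: int = 6
    n_candidates: int = 50
    n_retained: int = 3
    tax_weight: float = 1.0          # tau: scale of the taxonomic bonus
    consensus_bonus: float = 0.1     # per ontology level matching the consensus
    consensus_radius: int = 1        # neighborhood hops pooled for the consensus
    identity_tol_ppm: float = 20.0
    identity_min_score: float = 0.8
    adducts: tuple[tuple[str, float], ...] = DEFAULT_ADDUCTS

    def __post_init__(self):
        if self.n_retained > self.n_candidates:
            raise ValueError("n_retained must be <= n_candidates")
        for v in (self.parent_tol_da, self.msms_tol_da, self.identity_tol_ppm):
            if v <= 0:
                raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class LibraryEntry:
    """A structure-organism pair with its reference spectrum and class triple."""

    structure_id: str
    name: str
    monoisotopic_mass: float
    spectrum: Spectrum
    class_triple: tuple[str, str, str]
    source_taxa: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic mass must be > 0")


# --------------------------------------------------------------------------
# Taxonomy
# --------------------------------------------------------------------------

@dataclass
class TaxonomyTree:
    """Rooted taxonomy with the seven classical ranks.

    nodes maps taxon_id -> (name, rank, parent_id); the single root has rank
    'root' and parent None. Distance between two taxa is the 0-based rank
    index (from species) of their lowest common ancestor's rank: 0 for the
    same species, 1 for congeners, ... 7 when only the root is shared.
    """

    nodes: dict[str, tuple[str, str, Optional[str]]]

    def __post_init__(self):
        roots = [t for t, (_, _, p) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        order = {r: i for i, r in enumerate(RANKS)}
        order["root"] = len(RANKS)
        for t, (_, rank, parent) in self.nodes.items():
            if parent is None:
                continue
            if parent not in self.nodes:
                raise ValueError(f"taxon {t}: unknown parent {parent}")
            prank = self.nodes[parent][1]
            if order.get(prank, -1) <= order.get(rank, -1):
                raise ValueError(f"taxon {t}: parent rank {prank} not above {rank}")

    def lineage(self, taxon: str) -> list[str]:
        if taxon not in self.nodes:
            raise KeyError(f"unknown taxon {taxon!r}")
        out = [taxon]
        while True:
            parent = self.nodes[out[-1]][2]
            if parent is None:
                return out
            out.append(parent)

    def ancestor_at_rank(self, taxon: str, rank: str) -> Optional[str]:
        for t in self.lineage(taxon):
            if self.nodes[t][1] == rank:
                return t
        return None

    def distance(self, a: str, b: str) -> int:
        la, lb = self.lineage(a), self.lineage(b)
        common = set(la) & set(lb)
        order = {r: i for i, r in enumerate(RANKS)}
        best = MAX_DISTANCE
        for t in common:
            rank = self.nodes[t][1]
            if rank in order:
                best = min(best, order[rank])
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = [{"taxon_id": t, "name": n, "rank": r, "parent_id": p or ""}
                for t, (n, r, p) in sorted(self.nodes.items())]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTree":
        nodes = {row.taxon_id: (row.name_, row.rank_, row.parent_id or None)
                 for row in df.rename(columns={"name": "name_", "rank": "rank_"})
                              .itertuples(index=False)}
        return cls(nodes=nodes)


def taxonomic_distance(taxon_a: str, taxon_b: str, tree: TaxonomyTree) -> int:
    """Rank steps from species (0) to the lowest common ancestor's rank."""
    return tree.distance(taxon_a, taxon_b)


def write_taxonomy(tree: TaxonomyTree, path) -> Path:
    path = Path(path)
    tree.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_taxonomy(path) -> TaxonomyTree:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return TaxonomyTree.from_frame(df)


# --------------------------------------------------------------------------
# Candidates
# --------------------------------------------------------------------------

@dataclass
class AnnotationCandidate:
    feature_id: str
    entry: LibraryEntry
    sigma: float                       # spectral score
    n_matched: int
    taxonomic_distance: Optional[int] = None
    final_score: float = 0.0
    rank: int = 0

    @property
    def structure_id(self) -> str:
        return self.entry.structure_id

    @property
    def class_triple(self) -> tuple[str, str, str]:
        return self.entry.class_triple


def ms1_adduct_match(
    precursor_mz: float,
    library: Sequence[LibraryEntry],
    sample_taxa: Iterable[str],
    tree: TaxonomyTree,
    params: Optional[AnnotationParams] = None,
) -> list[tuple[LibraryEntry, str, float]]:
    """MS1-level candidates: library entries for which some common adduct of
    the neutral mass matches the precursor within parent_tol_da AND whose
    source organisms fall in the taxonomic family of the analyzed sample.

    Returns (entry, adduct name, m/z error) triples sorted by |error|.
    """
    params = params or AnnotationParams()
    sample_taxa = list(sample_taxa)
    sample_families = set()
    for t in sample_taxa:
        if t not in tree.nodes:
            raise KeyError(f"unknown sample taxon {t!r}")
        fam = tree.ancestor_at_rank(t, "family")
        if fam is not None:
            sample_families.add(fam)
    out = []
    for entry in library:
        in_family = False
        for t in entry.source_taxa:
            if t in tree.nodes and tree.ancestor_at_rank(t, "family") in sample_families:
                in_family = True
                break
        if not in_family:
            continue
        for adduct, offset in params.adducts:
            err = abs(entry.monoisotopic_mass + offset - precursor_mz)
            if err <= params.parent_tol_da:
                out.append((entry, adduct, err))
    out.sort(key=lambda t: (t[2], t[0].structure_id))
    return out


def ms2_library_search(
    feature_id: str,
    spectrum: Optional[Spectrum],
    library: Sequence[LibraryEntry],
    params: Optional[AnnotationParams] = None,
) -> list[AnnotationCandidate]:
    """Spectral-library search: candidates within the parent-mass tolerance
    scoring sigma >= min_cosine with >= min_peaks matched peaks, sorted by
    sigma descending, truncated to n_candidates."""
    params = params or AnnotationParams()
    if spectrum is None:
        warnings.warn(f"feature {feature_id} has no MS/MS spectrum")
        return []
    cands = []
    for entry in library:
        if abs(entry.spectrum.precursor_mz - spectrum.precursor_mz) > params.parent_tol_da:
            continue
        m = modified_cosine(spectrum, entry.spectrum, tol_da=params.msms_tol_da)
        if m.score >= params.min_cosine and m.n_matched_peaks >= params.min_peaks:
            cands.append(AnnotationCandidate(
                feature_id=feature_id, entry=entry, sigma=m.score,
                n_matched=m.n_matched_peaks, final_score=m.score))
    cands.sort(key=lambda c: (-c.sigma, c.structure_id))
    for i, c in enumerate(cands[:params.n_candidates], start=1):
        c.rank = i
    return cands[:params.n_candidates]


def reweight_candidates(
    candidates: Sequence[AnnotationCandidate],
    sample_taxa: Iterable[str],
    tree: TaxonomyTree,
    params: Optional[AnnotationParams] = None,
) -> list[AnnotationCandidate]:
    """Taxonomically informed re-ranking.

    final_score = sigma + tau * (R - d) / R where d is the minimum taxonomic
    distance between the analyzed sample's taxa and any reported source
    taxon of the candidate (R = 7 when nothing below the root is shared, so
    the bonus vanishes for maximally distant sources). The candidate set is
    unchanged; the re-sort is stable.
    """
    params = params or AnnotationParams()
    sample_taxa = [t for t in sample_taxa if t]
    R = MAX_DISTANCE
    out = []
    for c in candidates:
        d = R
        for st in sample_taxa:
            for ct in c.entry.source_taxa:
                if ct in tree.nodes:
                    d = min(d, tree.distance(st, ct))
        final = c.sigma + params.tax_weight * (R - d) / R
        out.append(replace(c, taxonomic_distance=d, final_score=final))
    out.sort(key=lambda c: -c.final_score)  # stable: equal scores keep order
    for i, c in enumerate(out, start=1):
        c.rank = i
    return out


# --------------------------------------------------------------------------
# Consensus classes and identity
# --------------------------------------------------------------------------

LEVEL_NAMES = ("pathway", "superclass", "class")


def consensus_class(
    network: MolecularNetwork,
    candidates_per_node: Mapping[str, Sequence[AnnotationCandidate]],
    params: Optional[AnnotationParams] = None,
) -> dict[str, tuple[tuple[Optional[str], ...], list[AnnotationCandidate]]]:
    """Per-node consensus chemical class and consensus-bumped top candidates.

    For each node the rank-1 candidate of the node itself and of every
    neighbor within consensus_radius hops votes for its class triple,
    weighted by final_score; the top-total label per level is the consensus
    (ties: lexicographically smallest label). Candidates then receive
    consensus_bonus per level on which their triple matches the consensus,
    are re-sorted, and the top n_retained are kept.
    """
    params = params or AnnotationParams()
    g = network.graph
    result = {}
    for node in g.nodes:
        voters = {node}
        frontier = {node}
        for _ in range(params.consensus_radius):
            frontier = {nb for f in frontier for nb in g.neighbors(f)} - voters
            voters |= frontier
        tallies: list[dict[str, float]] = [{}, {}, {}]
        for voter in sorted(voters):
            cands = candidates_per_node.get(voter, [])
            if not cands:
                continue
            top = cands[0]
            for lvl, label in enumerate(top.class_triple):
                tallies[lvl][label] = tallies[lvl].get(label, 0.0) + top.final_score
        consensus = tuple(
            min((lab for lab, w in t.items() if w == max(t.values())))
            if t else None
            for t in tallies)
        bumped = []
        for c in candidates_per_node.get(node, []):
            n_match = sum(1 for lvl in range(3)
                          if consensus[lvl] is not None
                          and c.class_triple[lvl] == consensus[lvl])
            bumped.append(replace(c, final_score=c.final_score
                                  + params.consensus_bonus * n_match))
        bumped.sort(key=lambda c: -c.final_score)
        for i, c in enumerate(bumped, start=1):
            c.rank = i
        result[node] = (consensus, bumped[:params.n_retained])
    return result


@dataclass(frozen=True)
class Identity:
    structure_id: str
    name: str
    score: float
    n_matched: int


def identity_match(
    spectrum: Optional[Spectrum],
    standards: Sequence[LibraryEntry],
    params: Optional[AnnotationParams] = None,
) -> Optional[Identity]:
    """Confirmed-tier identification against a standards library: precursor
    within identity_tol_ppm and plain cosine >= identity_min_score."""
    params = params or AnnotationParams()
    if spectrum is None:
        return None
    best = None
    for entry in standards:
        if ppm_diff(entry.spectrum.precursor_mz, spectrum.precursor_mz) > params.identity_tol_ppm:
            continue
        m = cosine_direct(spectrum, entry.spectrum, tol_da=params.msms_tol_da)
        if m.score >= params.identity_min_score:
            if best is None or (m.score, entry.structure_id) > (best[0], best[1].structure_id):
                best = (m.score, entry, m.n_matched_peaks)
    if best is None:
        return None
    score, entry, n = best
    return Identity(structure_id=entry.structure_id, name=entry.name,
                    score=score, n_matched=n)


# --------------------------------------------------------------------------
# Dataset-level cascade
# --------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    feature_id: str
    tier: str                                  # "confirmed" | "annotated" | "unannotated"
    identity: Optional[Identity]
    candidates: list[AnnotationCandidate]
    consensus_triple: tuple[Optional[str], ...]


def annotate_dataset(
    table,
    network: MolecularNetwork,
    library: Sequence[LibraryEntry],
    tree: TaxonomyTree,
    standards: Sequence[LibraryEntry] = (),
    params: Optional[AnnotationParams] = None,
) -> tuple[dict[str, AnnotationRecord], dict[str, float]]:
    """Run the full cascade on every feature of a table.

    The sample taxa of a feature are those of the samples in which it is
    called present. Returns (records by feature id, coverage stats: fraction
    of features with a consensus label per ontology level and the confirmed/
    annotated fractions).
    """
    params = params or AnnotationParams()
    presence = table.presence
    taxa_of_sample = table.meta["taxon_id"].to_dict()

    reweighted: dict[str, list[AnnotationCandidate]] = {}
    identities: dict[str, Identity] = {}
    for fid in table.features.index:
        spec = table.spectra.get(fid)
        if presence is not None:
            samples = [s for s in presence.columns if presence.loc[fid, s]]
        else:
            samples = list(table.sample_ids)
        sample_taxa = sorted({taxa_of_sample.get(s, "") for s in samples} - {""})
        ident = identity_match(spec, standards, params) if standards else None
        if ident is not None:
            identities[fid] = ident
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = ms2_library_search(fid, spec, library, params)
        reweighted[fid] = reweight_candidates(cands, sample_taxa, tree, params)

    consensus = consensus_class(network, reweighted, params)
    records: dict[str, AnnotationRecord] = {}
    for fid in table.features.index:
        cons, top = consensus.get(fid, ((None, None, None), []))
        if fid in identities:
            tier = "confirmed"
        elif top:
            tier = "annotated"
        else:
            tier = "unannotated"
        records[fid] = AnnotationRecord(
            feature_id=fid, tier=tier, identity=identities.get(fid),
            candidates=top, consensus_triple=cons)

    n = max(len(records), 1)
    stats = {
        "fraction_confirmed": sum(r.tier == "confirmed" for r in records.values()) / n,
        "fraction_annotated": sum(r.tier != "unannotated" for r in records.values()) / n,
    }
    for lvl, name in enumerate(LEVEL_NAMES):
        stats[f"fraction_with_{name}"] = sum(
            r.consensus_triple[lvl] is not None for r in records.values()) / n
    return records, stats


def annotations_to_frame(records: Mapping[str, AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records to the TSV layout (one row per retained
    candidate, plus one row for unannotated features)."""
    rows = []
    for fid in sorted(records):
        r = records[fid]
        base = {"feature_id": fid, "tier": r.tier,
                "pathway": r.consensus_triple[0], "superclass": r.consensus_triple[1],
                "class": r.consensus_triple[2]}
        if not r.candidates:
            rows.append({**base, "rank": None, "structure_id": None,
                         "sigma": None, "distance": None, "final_score": None})
        for c in r.candidates:
            rows.append({**base, "rank": c.rank, "structure_id": c.structure_id,
                         "sigma": c.sigma, "distance": c.taxonomic_distance,
                         "final_score": c.final_score})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Library I/O
# --------------------------------------------------------------------------

def write_library(entries: Sequence[LibraryEntry], directory, name: str = "library") -> dict:
    """Write a reference library as an MGF (spectra) + TSV (structure,
    class triple, source taxa) pair."""
    from pyteomics import mgf as _mgf
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mgf_path = directory / f"{name}.mgf"
    specs = [{
        "m/z array": e.spectrum.mz,
        "intensity array": e.spectrum.intensities,
        "params": {"TITLE": e.structure_id,
                   "PEPMASS": f"{e.spectrum.precursor_mz!r}",
                   "RTINSECONDS": e.spectrum.rt * 60.0, "CHARGE": "1+"},
    } for e in entries]
    with open(mgf_path, "w") as fh:
        _mgf.write(specs, fh)
    tsv_path = directory / f"{name}.tsv"
    pd.DataFrame([{
        "structure_id": e.structure_id, "name": e.name,
        "monoisotopic_mass": e.monoisotopic_mass,
        "pathway": e.class_triple[0], "superclass": e.class_triple[1],
        "class": e.class_triple[2],
        "source_taxa": "|".join(sorted(e.source_taxa)),
    } for e in entries]).to_csv(tsv_path, sep="\t", index=False)
    return {"mgf": mgf_path, "tsv": tsv_path}


def read_library(mgf_path, tsv_path) -> list[LibraryEntry]:
    from pyteomics import mgf as _mgf
    meta = pd.read_csv(tsv_path, sep="\t", keep_default_na=False).set_index("structure_id")
    entries = []
    with _mgf.MGF(str(mgf_path)) as reader:
        for entry in reader:
            sid = str(entry["params"]["title"])
            row = meta.loc[sid]
            spec = Spectrum(
                precursor_mz=float(entry["params"]["pepmass"][0]),
                rt=float(entry["params"].get("rtinseconds", 0.0)) / 60.0,
                mz=np.asarray(entry["m/z array"], dtype=float),
                intensities=np.asarray(entry["intensity array"], dtype=float))
            taxa = frozenset(t for t in str(row["source_taxa"]).split("|") if t)
            entries.append(LibraryEntry(
                structure_id=sid, name=str(row["name"]),
                monoisotopic_mass=float(row["monoisotopic_mass"]),
                spectrum=spec,
                class_triple=(row["pathway"], row["superclass"], row["class"]),
                source_taxa=taxa))
    return entries


def write_msp(entries: Sequence[LibraryEntry], path) -> Path:
    """Write a standards library in MSP format (matchms dialect)."""
    from matchms import Spectrum as MSpectrum
    from matchms.exporting import save_as_msp
    specs = []
    for e in entries:
        specs.append(MSpectrum(
            mz=np.asarray(e.spectrum.mz, dtype=float),
            intensities=np.asarray(e.spectrum.intensities, dtype=float),
            metadata={"compound_name": e.name, "precursor_mz": e.spectrum.precursor_mz,
                      "structure_id": e.structure_id,
                      "monoisotopic_mass": e.monoisotopic_mass},
            metadata_harmonization=False))
    path = Path(path)
    if path.exists():
        path.unlink()
    save_as_msp(specs, str(path))
    return path


def read_msp(path) -> list[LibraryEntry]:
    from matchms.importing import load_from_msp
    entries = []
    for s in load_from_msp(str(path), metadata_harmonization=False):
        md = s.metadata
        spec = Spectrum(precursor_mz=float(md["precursor_mz"]), rt=0.0,
                        mz=np.asarray(s.peaks.mz, dtype=float),
                        intensities=np.asarray(s.peaks.intensities, dtype=float))
        sid = str(md.get("structure_id", md.get("compound_name")))
        entries.append(LibraryEntry(
            structure_id=sid, name=str(md.get("compound_name", sid)),
            monoisotopic_mass=float(md.get("monoisotopic_mass",
                                           spec.precursor_mz - 1.007276)),
            spectrum=spec, class_triple=("", "", ""), source_taxa=frozenset()))
    return entries
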