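import numpy as np
import pandas as pd
import pytest

from holometab.core import SampleFeature, Spectrum
from holometab.features import FeatureTable, process_dataset
from holometab.msnet import build_network
from holometab.synthio import (NoiseModel, StudyDesign, default_strains,
                               generate_metabolome, generate_ontology,
                               make_library, make_taxonomy, simulate_samples)

SMALL_COUNTS = {"host_only": 10, "strain_specific": 6,
                "multi_strain": 2, "shared_host_strain": 4}


def small_design(noise=None, seed=3, **kw):
    """A scaled-down study (6 strains, 10 fractions) for fast unit tests."""
    kw.setdefault("strains", default_strains(6))
    kw.setdefault("n_fractions", 10)
    return StudyDesign(noise=noise or NoiseModel.zero(), seed=seed, **kw)


@pytest.fixture(scope="session")
def ontology():
    return generate_ontology(5, 3, seed=1)


@pytest.fixture(scope="session")
def zero_noise_study(ontology):
    design = small_design()
    truth = generate_metabolome(ontology, design, SMALL_COUNTS, seed=3)
    samples, metadata = simulate_samples(truth)
    return truth, samples, metadata


@pytest.fixture(scope="session")
def processed(zero_noise_study):
    truth, samples, metadata = zero_noise_study
    general, fungal, host = process_dataset(samples, metadata)
    return general, fungal, host


@pytest.fixture(scope="session")
def network(processed):
    general, _, _ = processed
    return build_network(general)


@pytest.fixture(scope="session")
def library_and_tree(zero_noise_study):
    truth, _, _ = zero_noise_study
    return make_library(truth), make_taxonomy(truth.design)


def mk_feature(fid, mz, rt, intensity=100.0, sample="S1", rep=1, spectrum="auto"):
    if spectrum == "auto":
        spectrum = Spectrum(precursor_mz=mz, rt=rt,
                            mz=np.array([50.0, 60.0]), intensities=np.array([1.0, 0.5]))
    return SampleFeature(feature_id=fid, sample_id=sample, replicate=rep,
                         mz=mz, rt=rt, intensity=intensity, spectrum=spectrum)


def build_table(intensities: dict, meta_types: dict,
                n_replicates: int = 3) -> FeatureTable:
    """Construct a FeatureTable directly from
    {row_id: {(sample, rep): intensity}} and {sample: sample_type}."""
    cols = pd.MultiIndex.from_tuples(
        [(s, r) for s in meta_types for r in range(1, n_replicates + 1)],
        names=["sample_id", "replicate"])
    rows = sorted(intensities)
    inten = pd.DataFrame(0.0, index=rows, columns=cols)
    for rid, cells in intensities.items():
        for key, val in cells.items():
            inten.loc[rid, key] = val
    feats = pd.DataFrame({"mz": np.linspace(200, 300, len(rows)),
                          "rt": np.linspace(1, 5, len(rows))}, index=rows)
    meta = pd.DataFrame({
        "sample_type": pd.Series(meta_types),
        "organism": {s: (s.split("_")[0] if t == "fungal" else
                         ("host" if t.startswith("host") else ""))
                     for s, t in meta_types.items()},
        "taxon_id": {s: "" for s in meta_types},
    })
    meta.index.name = "sample_id"
    return FeatureTable(features=feats, intensities=inten,
                        detection=inten > 0, meta=meta)
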