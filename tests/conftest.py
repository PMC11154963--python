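"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wwscreen.components import AlignedComponent, Component, MEASURED
from wwscreen.io_formats import FeatureRecord, Spectrum
from wwscreen.registry import SuspectEntry, default_adducts
from wwscreen.screening import SuspectHit
from wwscreen.synthetic import GeneratorConfig, generate_dataset

MH = [a for a in default_adducts("positive") if a.label == "[M+H]+"][0]


def random_spectrum(rng: np.random.Generator, identifier: str,
                    max_peaks: int = 20) -> Spectrum:
    """Random but valid spectrum with grid-rounded values (exact roundtrip)."""
    n = int(rng.integers(0, max_peaks + 1))
    peaks = sorted(
        {
            (round(float(rng.uniform(50, 950)), 5),
             round(float(rng.uniform(0, 1e6)), 3))
            for _ in range(n)
        }
    )
    annotations = {}
    if rng.random() < 0.5:
        annotations["Formula"] = "C10H12N2O"
    if rng.random() < 0.3:
        annotations["Comment"] = f"replicate {int(rng.integers(0, 9))}"
    return Spectrum(
        identifier=identifier,
        precursor_mz=round(float(rng.uniform(100, 1000)), 5),
        polarity="positive" if rng.random() < 0.5 else "negative",
        rt=round(float(rng.uniform(0, 34)), 4) if rng.random() < 0.8 else None,
        peaks=peaks,
        annotations=annotations,
    )


def make_component(
    mz: float = 242.11756,
    rt: float = 10.0,
    sample_intensity: dict[str, float] | None = None,
    peak_rating: float = 8.0,
    ms2: Spectrum | None = None,
    row_id: int = 0,
) -> AlignedComponent:
    sample_intensity = sample_intensity or {"S1": 5e5}
    members = []
    for i, (sample, inten) in enumerate(sorted(sample_intensity.items())):
        members.append(
            Component(
                component_id=f"{sample}:{row_id}",
                representative_mz=mz,
                rt=rt,
                sample_id=sample,
                intensity=inten,
                peak_rating=peak_rating,
                ms2=ms2 if i == 0 else None,
            )
        )
    return AlignedComponent(
        row_id=row_id,
        mz=mz,
        rt=rt,
        intensity=dict(sample_intensity),
        provenance={s: MEASURED for s in sample_intensity},
        peak_rating=peak_rating,
        members=members,
    )


def make_hit(
    suspect: SuspectEntry | None = None,
    mz: float = 242.11756,
    rt: float = 10.0,
    sample_intensity: dict[str, float] | None = None,
    peak_rating: float = 8.0,
    ms2: Spectrum | None = None,
    ppm: float = 0.0,
    row_id: int = 0,
) -> SuspectHit:
    suspect = suspect or SuspectEntry("mefenamic_acid", "C15H15NO2", logD_pos=5.0)
    comp = make_component(mz, rt, sample_intensity, peak_rating, ms2, row_id)
    return SuspectHit(component=comp, suspect=suspect, adduct=MH, ppm_error=ppm)


def tiny_ms2(identifier: str = "sp", precursor: float = 242.11756,
             peaks=None) -> Spectrum:
    return Spectrum(
        identifier=identifier,
        precursor_mz=precursor,
        peaks=peaks or [(100.0, 1.0), (150.0, 2.0)],
    )


@pytest.fixture(scope="session")
def demo_dataset():
    """One synthetic campaign at the default study conditions."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def demo_result(demo_dataset):
    from wwscreen.pipeline import run_pipeline

    return run_pipeline(demo_dataset)
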