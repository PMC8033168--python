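"""Shared fixtures.

The expensive fixture is the "default cohort": 50 + 50 simulated cells
(compact 31x31 px grids, default noise, planted 786 cm^-1 effect 0.8) pushed
through the full segmentation stage once per session and reused by the
classifier, cross-modal and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ramanxome as rx

COHORT_SEED = 11
SEGMENT_SEED = 0


@pytest.fixture(scope="session")
def library():
    return rx.synthetic.make_component_library()


@pytest.fixture(scope="session")
def axis(library):
    return library.axis


@pytest.fixture(scope="session")
def default_cohort():
    """50+50-cell default cohort with ground truth, segmented end to end."""
    maps, truth = rx.synthetic.simulate_cohort(
        50, 50, rx.synthetic.GeometrySampler.small(), noise_sd=rx.synthetic.DEFAULT_NOISE_SD,
        seed=COHORT_SEED,
    )
    with np.errstate(all="ignore"):
        result = rx.segmentation.segment_cohort(maps, k=10, seed=SEGMENT_SEED, n_init=3)
    return {"maps": maps, "truth": truth, "segmentation": result}


@pytest.fixture(scope="session")
def nucleus_analysis(default_cohort):
    """PCA + LDA + pseudo-replicates on the default cohort's nucleus spectra."""
    seg = default_cohort["segmentation"]
    X, labels, ids = seg.spectra_matrix("nucleus")
    pcm = rx.spectral.fit_pca(X, n_keep=9)
    ldm = rx.spectral.fit_lda(pcm, labels)
    reps = rx.crossmodal.make_pseudoreplicates(pcm.kept_scores, labels, n_groups=3, seed=7)
    return {"X": X, "labels": labels, "ids": ids, "pcm": pcm, "ldm": ldm, "reps": reps}


@pytest.fixture(scope="session")
def linked_counts(nucleus_analysis):
    """Default 30-of-2000 planted count matrix tied to the cohort's Raman axes."""
    cm, truth = rx.synthetic.simulate_transcriptome(
        2000, 30, nucleus_analysis["reps"].group_means, dispersion=0.05, seed=23
    )
    return {"counts": cm, "truth": truth}
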