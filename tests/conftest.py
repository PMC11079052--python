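import dataclasses

import numpy as np
import pytest

import chromofoci as cf


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free five-nucleus scene with colocalized reporter."""
    params = cf.SceneParams(nucleus_count=5, foci_per_nucleus_mean=5.0,
                            dna_foci_to_nucleoplasm_contrast=3.0, seed=11)
    channels, truth = cf.simulate_scene(params)
    return params, channels, truth


@pytest.fixture(scope="session")
def slow_noisy_fit():
    """One noisy slow-regime trace taken through normalize + fit."""
    params = dataclasses.replace(cf.SLOW_REGIME, noise_sd=0.02, seed=5)
    trace = cf.simulate_frap_trace(params)
    nt = cf.normalize_frap(trace)
    return params, nt, cf.fit_two_phase(nt)


def pairwise_jaccard(labels: np.ndarray, truth_mask: np.ndarray) -> list[float]:
    """Jaccard of each ground-truth nucleus with its best-overlapping label."""
    out = []
    for lab in range(1, int(truth_mask.max()) + 1):
        g = truth_mask == lab
        vals = labels[g]
        fg = vals[vals > 0]
        if fg.size == 0:
            out.append(0.0)
            continue
        cand = np.bincount(fg).argmax()
        m = labels == cand
        out.append(float((g & m).sum() / (g | m).sum()))
    return out
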