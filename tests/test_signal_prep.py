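"""Decimation, coarse graining and fiducial detection contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from paflz.signal_prep import (
    FiducialSet,
    beat_detection_binarize,
    decimate,
    detect_fiducials,
    feature_detection_binarize,
    kmeans_binarize,
    threshold_crossing,
)

from _oracles import two_means_oracle

signals = hnp.arrays(
    dtype=float,
    shape=st.integers(2, 200),
    elements=st.floats(-10, 10, allow_nan=False),
)


# ---------------------------------------------------------------------------
# decimation


def test_decimate_lengths():
    x = np.arange(5000.0)
    assert decimate(x, 125).size == 1250
    assert decimate(x, 250).size == 2500
    assert decimate(x, 375).size == 3750
    assert decimate(x, 500).size == 5000


def test_decimate_identity_and_pattern():
    x = np.arange(8.0)
    assert np.array_equal(decimate(x, 500), x)
    # 375 Hz keeps 3 of every 4 samples, dropping indices == 3 mod 4
    assert np.array_equal(decimate(x, 375), [0, 1, 2, 4, 5, 6])
    assert np.array_equal(decimate(x, 125), [0, 4])


def test_decimate_keeps_index_zero_and_composes():
    x = np.sin(np.arange(5000) / 7.0)
    for f in (125, 250, 375):
        assert decimate(x, f)[0] == x[0]
    for f in (125, 250):
        assert np.array_equal(decimate(decimate(x, 500), f), decimate(x, f))


def test_decimate_works_on_lead_matrices():
    x = np.arange(24.0).reshape(2, 12)
    assert decimate(x, 125).shape == (2, 3)


def test_decimate_invalid_rate():
    with pytest.raises(ValueError):
        decimate(np.zeros(8), 100)
    with pytest.raises(ValueError):
        decimate(np.zeros(8), 125, source_fs=250)


# ---------------------------------------------------------------------------
# threshold crossing


@pytest.mark.parametrize(
    "x, expected",
    [
        ([1, 2, 3, 4], "0011"),
        ([1, 2, 2, 3], "0001"),  # points equal to the median map to 0
        ([5, 5, 5, 5], "0000"),
    ],
)
def test_threshold_crossing_examples(x, expected):
    assert threshold_crossing(x) == expected


@settings(derandomize=True, max_examples=100)
@given(signals)
def test_threshold_crossing_median_property(x):
    s = threshold_crossing(x)
    assert len(s) == x.size
    zeros = s.count("0")
    assert zeros >= int(np.ceil(x.size / 2))


def test_threshold_crossing_empty_rejected():
    with pytest.raises(ValueError):
        threshold_crossing([])


# ---------------------------------------------------------------------------
# k-means binarization


def test_kmeans_symmetric_two_cluster():
    assert kmeans_binarize([-1, -1, 1, 1]) == "0011"


def test_kmeans_constant_signal_all_zeros():
    assert kmeans_binarize([2.0] * 7) == "0000000"


def test_kmeans_matches_exhaustive_two_means_on_bimodal(rng):
    x = np.concatenate(
        [rng.normal(-1.0, 0.1, 500), rng.normal(1.0, 0.1, 500)]
    )
    rng.shuffle(x)
    got = [int(c) for c in kmeans_binarize(x)]
    assert got == two_means_oracle(x)


def test_kmeans_invalid_params():
    with pytest.raises(ValueError):
        kmeans_binarize([1.0, 2.0], init_deflection=-1)
    with pytest.raises(ValueError):
        kmeans_binarize([1.0])


# ---------------------------------------------------------------------------
# fiducial detection


def test_detects_ground_truth_r_peaks(clean_record):
    x = clean_record.lead("II")
    fid = detect_fiducials(x, 500)
    true = clean_record.fiducials["II"]
    assert 9 <= fid.n_beats <= 10
    det = fid.r_indices()
    tru = true.r_indices()
    assert det.size == tru.size
    assert np.max(np.abs(det - tru)) <= 2


def test_all_waves_near_ground_truth(clean_record):
    x = clean_record.lead("II")
    fid = detect_fiducials(x, 500)
    true = clean_record.fiducials["II"]
    # Q and S ride on the R upstroke/downstroke, so the extremum of the
    # summed waveform is shifted away from the component center
    tolerances = {"p": 2, "q": 8, "r": 2, "s": 8, "t": 2}
    for wave, tol in tolerances.items():
        det = [i for i in getattr(fid, wave) if i is not None]
        tru = [i for i in getattr(true, wave) if i is not None]
        assert len(det) == len(tru)
        assert max(abs(a - b) for a, b in zip(det, tru)) <= tol, wave


def test_detection_consistent_after_decimation(clean_record):
    x = clean_record.lead("II")
    tru = clean_record.fiducials["II"].r_indices()
    for f, step in ((125, 4), (250, 2)):
        det = detect_fiducials(decimate(x, f), f).r_indices()
        scaled = np.round(tru / step).astype(int)
        assert det.size == scaled.size
        assert np.max(np.abs(det - scaled)) <= 2


def test_flat_line_gives_empty_fiducials():
    fid = detect_fiducials(np.zeros(2000), 500)
    assert fid.n_beats == 0


def test_fiducialset_validates_ordering():
    with pytest.raises(ValueError):
        FiducialSet(fs=500, p=(50,), q=(40,), r=(60,), s=(70,), t=(80,))
    with pytest.raises(ValueError):
        FiducialSet(fs=500, p=(1,), q=(2,), r=(3,), s=(4,), t=())


# ---------------------------------------------------------------------------
# fiducial-driven binarizers


def test_feature_and_beat_strings(clean_record):
    n = clean_record.n_samples
    fid = clean_record.fiducials["II"]
    fd = feature_detection_binarize(fid, n)
    bd = beat_detection_binarize(fid, n)
    assert len(fd) == len(bd) == n
    assert fd.count("1") == fid.all_indices().size
    assert bd.count("1") == fid.n_beats
    # BD ones are a subset of FD ones
    assert all(fd[i] == "1" for i, c in enumerate(bd) if c == "1")


def test_two_beats_all_waves_gives_ten_ones():
    fid = FiducialSet(
        fs=500,
        p=(10, 510), q=(20, 520), r=(30, 530), s=(40, 540), t=(50, 550),
    )
    assert feature_detection_binarize(fid, 600).count("1") == 10


def test_empty_fiducials_give_all_zeros():
    fid = FiducialSet(fs=500)
    assert set(feature_detection_binarize(fid, 100)) == {"0"}
    assert set(beat_detection_binarize(fid, 100)) == {"0"}


def test_out_of_range_index_rejected():
    fid = FiducialSet(fs=500, p=(None,), q=(None,), r=(99,), s=(None,), t=(None,))
    with pytest.raises(ValueError):
        beat_detection_binarize(fid, 50)


def test_ones_count_invariant_across_frequencies(clean_record):
    """The number of ones from the same record is frequency independent."""
    counts = set()
    for f in (125, 250, 375, 500):
        x = decimate(clean_record.lead("II"), f)
        fid = detect_fiducials(x, f)
        counts.add(beat_detection_binarize(fid, x.size).count("1"))
    assert len(counts) == 1
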