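import numpy as np
import pandas as pd
import pytest

from aktdyn.peaks import peak_features
from aktdyn.splines import MEASUREMENT_GRID
from aktdyn.synth import (
    NoiseModel,
    add_replicate_noise,
    densitometry_normalize,
    default_truth_spec,
    generate_ground_truth,
    generate_pip3_input,
    make_fixture_bundle,
)

GRID = list(MEASUREMENT_GRID)


def test_pip3_input_shape():
    curve = generate_pip3_input()
    values = np.asarray(curve.knot_values)
    assert curve.knot_times[int(np.argmax(values))] == 2.0
    # plateau strictly between baseline and peak
    assert values[0] < values[-1] < values.max()
    assert generate_pip3_input(baseline=0.0).knot_values[0] == 0.0


def test_ground_truth_reproduces_shape_anchors(noiseless_bundle):
    aktp308 = noiseless_bundle.dataset("aktp308").series("Aktp308", "serum")
    assert peak_features(aktp308.index, aktp308.to_numpy()).peak_time == 30.0
    totmem = noiseless_bundle.dataset("membrane").series("TotMemAkt", "serum")
    assert peak_features(totmem.index, totmem.to_numpy()).peak_time == 5.0
    pdk1m = noiseless_bundle.dataset("membrane").series("PDK1m", "serum")
    assert pdk1m.idxmax() == 2.0


def test_normalization_maxima(noiseless_bundle):
    assert noiseless_bundle.dataset("aktp308").series("Aktp308", "serum").max() \
        == pytest.approx(10.0)
    membrane = noiseless_bundle.dataset("membrane")
    assert membrane.series("TotMemAkt", "serum").max() == pytest.approx(10.0)
    assert membrane.series("Aktp308m", "serum").max() == pytest.approx(5.0)


def test_membrane_capped_by_lysate(noiseless_bundle):
    lysate = noiseless_bundle.dataset("aktp308").series("Aktp308", "serum")
    memb = noiseless_bundle.dataset("membrane").series("Aktp308m", "serum")
    assert np.all(memb.to_numpy() <= lysate.to_numpy() + 1e-9)


def test_zero_noise_reproduces_truth_shape(truth_spec):
    trajs = generate_ground_truth(truth_spec)
    truth = trajs["serum"].at(GRID, "Aktp308")
    series = make_fixture_bundle(3, noise=NoiseModel(0, 0, 0)) \
        .dataset("aktp308").series("Aktp308", "serum")
    np.testing.assert_allclose(series.to_numpy(), truth * 10.0 / truth.max(),
                               rtol=1e-9)


def test_bundle_reproducible_and_seed_sensitive():
    a = make_fixture_bundle(1)
    b = make_fixture_bundle(1)
    c = make_fixture_bundle(2)
    va = a.dataset("aktp308").records["value"].to_numpy()
    vb = b.dataset("aktp308").records["value"].to_numpy()
    vc = c.dataset("aktp308").records["value"].to_numpy()
    np.testing.assert_array_equal(va, vb)
    assert not np.array_equal(va, vc)


def test_replicate_noise_median_tracks_truth():
    rng = np.random.default_rng(12)
    truth = np.array([1.0, 4.0, 8.0, 6.0])
    reps = add_replicate_noise([0, 2, 5, 10], truth, NoiseModel(0.2, 0.0, 0.0),
                               1000, rng)
    med = reps.groupby("time_min")["value"].median().to_numpy()
    # lognormal(sigma) has median 1, so the per-timepoint sample median
    # should sit within a few percent of the truth
    np.testing.assert_allclose(med, truth, rtol=0.03)


def test_fold_change_anchors_time_zero():
    """Noiseless chain: fold-change is 1 at t = 0 for every replicate, so
    the rescaled series starts at target * x(0) / max(x)."""
    rng = np.random.default_rng(4)
    truth = np.array([2.0, 3.0, 9.0, 6.0, 4.5, 4.0, 3.6])
    reps = add_replicate_noise(GRID, truth, NoiseModel(0, 0, 0), 4, rng)
    series = densitometry_normalize(reps, target_max=10.0).series("Aktp308", "serum")
    assert series.loc[0.0] == pytest.approx(10.0 * truth[0] / truth.max())
    assert series.max() == pytest.approx(10.0)


def test_normalization_chain_scale_invariant():
    rng = np.random.default_rng(9)
    truth = np.array([1.0, 3.0, 9.0, 6.0, 4.0, 3.5, 3.0])
    reps = add_replicate_noise(GRID, truth, NoiseModel(0.2, 0.15, 0.05), 5, rng)
    scaled = reps.copy()
    scaled["value"] *= 137.0
    a = densitometry_normalize(reps, 10.0).series(reps["species"].iloc[0], "serum")
    b = densitometry_normalize(scaled, 10.0).series(reps["species"].iloc[0], "serum")
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)


def test_normalize_rejects_nonpositive_control():
    df = pd.DataFrame({
        "species": "X", "condition": "serum", "replicate": 1,
        "time_min": [0, 2], "value": [1.0, 2.0], "control": [1.0, 0.0],
    })
    with pytest.raises(ValueError):
        densitometry_normalize(df, 10.0)


def test_bundle_write_round_trips(tmp_path, noiseless_bundle):
    noiseless_bundle.write(tmp_path / "bundle")
    assert (tmp_path / "bundle" / "manifest.json").exists()
    from aktdyn.data import read_timeseries
    back = read_timeseries(tmp_path / "bundle" / "aktp308.csv")
    orig = noiseless_bundle.dataset("aktp308")
    np.testing.assert_allclose(back.records["value"], orig.records["value"])


def test_intervention_conditions_in_ground_truth(truth_spec):
    trajs = generate_ground_truth(truth_spec)
    assert set(trajs) == {"serum", "ly29", "shutdown"}
    # clamped PIP3 keeps membrane Akt near its starved level
    ly29 = trajs["ly29"].observables["TotMemAkt"]
    assert ly29.max() - ly29.iloc[0] < 2.0
    # shutdown starts activated and keeps most membrane Akt while PDK1m goes
    shut = trajs["shutdown"]
    assert shut.observables["TotMemAkt"].iloc[0] > 5.0
    akt_pers = shut.at([120.0], "TotMemAkt")[0] / shut.observables["TotMemAkt"].iloc[0]
    pdk_pers = shut.at([120.0], "PDK1m")[0] / shut.observables["PDK1m"].iloc[0]
    assert akt_pers > 0.3
    assert pdk_pers < 0.05
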