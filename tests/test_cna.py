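"""Read-depth binning, RT correction, segmentation, and origin calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from clonotrace.cna import (
    CNASegment,
    CNAThresholds,
    bin_depth,
    classify_origin,
    rt_correct,
    segment_and_call,
)
from clonotrace.errors import DataError, ValidationError
from clonotrace.synthetic import (
    CONTROL_IPSC_SAMPLE,
    CONTROL_SAMPLE,
    DepthProfile,
    SimConfig,
    simulate_depth_and_rt,
)


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def test_bin_depth_constant_coverage():
    cov = track([("chr1", 0, 10_000, 7.0)])
    prof = bin_depth(cov, 1000)
    assert np.allclose(prof.bins["depth"], 7.0)
    assert len(prof.bins) == 10


def test_bin_depth_step_function_across_boundary():
    cov = track([("chr1", 0, 1000, 4.0), ("chr1", 1000, 2000, 10.0)])
    prof = bin_depth(cov, 1000)
    assert list(prof.bins["depth"]) == [4.0, 10.0]


def test_bin_depth_matches_bruteforce_average(rng):
    """Bin means equal per-position averages computed by brute force."""
    edges = np.sort(rng.choice(np.arange(1, 5000), size=40, replace=False))
    bounds = np.concatenate([[0], edges, [5000]])
    vals = rng.uniform(0, 20, size=len(bounds) - 1)
    cov = track([("chr1", int(s), int(e), float(v))
                 for s, e, v in zip(bounds[:-1], bounds[1:], vals)])
    prof = bin_depth(cov, 500)
    per_pos = np.repeat(vals, np.diff(bounds).astype(int))
    expected = per_pos.reshape(10, 500).mean(axis=1)
    assert np.allclose(prof.bins["depth"], expected)


def test_bin_depth_masks_sparse_bins_and_rejects_unsorted():
    cov = track([("chr1", 0, 400, 5.0), ("chr1", 1000, 2000, 5.0)])
    prof = bin_depth(cov, 1000)
    assert np.isnan(prof.bins["depth"].iloc[0])  # 40% covered -> masked
    assert prof.bins["depth"].iloc[1] == 5.0
    with pytest.raises(DataError):
        bin_depth(track([("chr1", 1000, 2000, 1.0), ("chr1", 0, 500, 1.0)]), 500)
    with pytest.raises(ValidationError):
        bin_depth(cov, 0)


def profile_from(depths, sample_type="pluripotent", sample_id="s"):
    n = len(depths)
    bins = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 1000,
        "end": (np.arange(n) + 1) * 1000,
        "depth": np.asarray(depths, dtype=float),
    })
    return DepthProfile(bins=bins, bin_size=1000, sample_id=sample_id,
                        sample_type=sample_type)


def test_rt_correct_self_is_zero():
    p = profile_from(np.linspace(10, 50, 30))
    out = rt_correct(p, p)
    assert np.allclose(out["log2_ratio"], 0.0)


def test_rt_correct_requires_pluripotent_control():
    p = profile_from([30] * 20)
    nsc = profile_from([30] * 20, sample_type="somatic")
    with pytest.raises(ValidationError):
        rt_correct(p, nsc)


def test_rt_correct_rejects_mismatched_bins():
    with pytest.raises(DataError):
        rt_correct(profile_from([30] * 20), profile_from([30] * 21))


def test_rt_correct_masks_low_control_depth():
    s = profile_from([30] * 10)
    c = profile_from([30] * 9 + [1])
    out = rt_correct(s, c, min_control_depth=5.0)
    assert np.isnan(out["log2_ratio"].iloc[-1])
    assert np.isfinite(out["log2_ratio"].iloc[:-1]).all()


def test_rt_correction_removes_rt_dosage(gain_config):
    """Raw depth vs a non-pluripotent control tracks the RT signal;
    normalising by the pluripotent control removes it."""
    profiles, rt = simulate_depth_and_rt(gain_config)
    z = rt.bins["value"].to_numpy()
    a = profiles["iPSC-1"]
    raw = np.log2(a.bins["depth"].to_numpy()
                  / profiles[CONTROL_SAMPLE].bins["depth"].to_numpy())
    corrected = rt_correct(a, profiles[CONTROL_IPSC_SAMPLE])["log2_ratio"]
    assert abs(spearmanr(raw, z).statistic) > 0.5
    assert abs(spearmanr(corrected, z).statistic) < 0.1


def test_shared_gain_recovered_with_pre_existing_origin(gain_config):
    profiles, _ = simulate_depth_and_rt(gain_config)
    ctrl = profiles[CONTROL_IPSC_SAMPLE]
    segs = {}
    for cid in ("iPSC-1", "iPSC-2"):
        segs[cid] = segment_and_call(
            rt_correct(profiles[cid], ctrl), sample_id=cid
        )
        assert len(segs[cid]) == 1
        seg = segs[cid][0]
        assert seg.call == "gain" and seg.chrom == "chr2"
        assert abs(seg.mean_log2_ratio - np.log2(1.5)) < 0.1
        assert abs(seg.fold_change - 1.5) < 0.11
    # reciprocal overlap between the two lines' calls >= 90%
    a, b = segs["iPSC-1"][0], segs["iPSC-2"][0]
    inter = min(a.end, b.end) - max(a.start, b.start)
    assert inter / max(a.length, b.length) >= 0.9

    nsc = profiles[CONTROL_SAMPLE].bins
    nsc_ratio = nsc[["chrom", "start", "end"]].assign(
        log2_ratio=np.log2(nsc["depth"] / np.nanmedian(nsc["depth"]))
    )
    segs_nsc = segment_and_call(nsc_ratio, sample_id=CONTROL_SAMPLE)
    somatic, excluded = classify_origin(segs["iPSC-1"], segs["iPSC-2"], segs_nsc)
    assert excluded == []
    assert all(s.origin == "pre_existing" for s in somatic)


def test_flat_profile_yields_no_segments():
    corr = profile_from([30] * 50).bins.rename(columns={"depth": "log2_ratio"})
    corr["log2_ratio"] = 0.01
    assert segment_and_call(corr) == []


def test_focal_event_below_min_length_not_called():
    corr = profile_from([0] * 50).bins.rename(columns={"depth": "log2_ratio"})
    corr.loc[10:11, "log2_ratio"] = 0.6  # 2 bins = 2 kb << 5 Mb
    assert segment_and_call(corr) == []
    th = CNAThresholds(min_segment_length=2000)
    segs = segment_and_call(corr, th)
    assert len(segs) == 1 and segs[0].call == "gain"


def test_segmentation_invariant_to_library_size(gain_config):
    profiles, _ = simulate_depth_and_rt(gain_config)
    a = profiles["iPSC-1"]
    ctrl = profiles[CONTROL_IPSC_SAMPLE]
    segs = segment_and_call(rt_correct(a, ctrl))
    scaled = DepthProfile(
        bins=a.bins.assign(depth=a.bins["depth"] * 3.7),
        bin_size=a.bin_size, sample_id=a.sample_id, sample_type=a.sample_type,
    )
    segs_scaled = segment_and_call(rt_correct(scaled, ctrl))
    assert [(s.chrom, s.start, s.end, s.call) for s in segs] == [
        (s.chrom, s.start, s.end, s.call) for s in segs_scaled
    ]


def test_median_centering_over_neutral_bins(gain_config):
    profiles, _ = simulate_depth_and_rt(gain_config)
    out = rt_correct(profiles["iPSC-1"], profiles[CONTROL_IPSC_SAMPLE])
    neutral = ~((out["chrom"] == "chr2")
                & (out["start"] >= 5e6) & (out["end"] <= 43e6))
    med = np.nanmedian(out.loc[neutral, "log2_ratio"])
    assert abs(med) < 0.02


def seg(chrom, start, end, call="gain", sample="A"):
    return CNASegment(chrom=chrom, start=start, end=end, mean_log2_ratio=0.6,
                      call=call, sample_id=sample)


def test_classify_origin_rules():
    shared_a = seg("chr1", 0, 10_000_000)
    shared_b = seg("chr1", 500_000, 10_200_000, sample="B")
    private_a = seg("chr2", 0, 8_000_000)
    germline = seg("chr3", 0, 9_000_000)
    germline_b = seg("chr3", 0, 9_000_000, sample="B")
    nsc = [seg("chr3", 0, 9_000_000, sample="NSC")]
    somatic, excluded = classify_origin(
        [shared_a, private_a, germline], [shared_b, germline_b], nsc
    )
    origins = {(s.sample_id, s.chrom): s.origin for s in somatic}
    assert origins[("A", "chr1")] == "pre_existing"
    assert origins[("B", "chr1")] == "pre_existing"
    assert origins[("A", "chr2")] == "post_reprogramming"
    assert {(s.sample_id, s.chrom) for s in excluded} == {("A", "chr3"), ("B", "chr3")}
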