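"""Self-contained validation benchmarks for every pipeline stage.

Each function regenerates synthetic data with known ground truth, runs the
relevant part of the pipeline from scratch, and returns summary metrics
(accuracies, detection rates, invariant magnitudes, calibration rates).
They are shared by the acceptance test suite and the reporting script; all
randomness derives from the single ``seed`` argument.
"""
from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

from . import quantify as _q
from . import simulate as _sim
from . import spatial as _sp
from . import lineage as _lin
from . import stats as _st
from . import regulatory as _reg


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ------------------------------------------------------------------ spatial


def inner_outer_recovery(seed: int, n_embryos: int = 20,
                         n_cells: int = 64) -> dict:
    """Inner/outer classification accuracy on shell-separated embryos.

    Embryos at the early-blastocyst scale (64 cells), inner cells at
    normalized radius <= 0.6, outer on the 0.8-1.0 surface shell, 1 µm
    centroid noise; plus semi-axis recovery on noise-free surface samples.
    """
    params = _sim.SimParams(
        seed=seed, n_embryos=n_embryos, n_cells_start=n_cells,
        n_cells_end=n_cells, division_rate=0.0, n_frames=1,
        reposition_prob=0.0, centroid_noise_sd=1.0,
    )
    nuclei, _, truth = _sim.simulate_embryo_series(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = _sp.classify_nucleus_table(nuclei)
    m = pos.merge(truth.labels, on=["embryo_id", "cell_id", "frame"])
    accuracy = float((m.in_out == m.true_label).mean())

    # axis recovery: noise-free samples on a rotated ellipsoid surface
    rng = np.random.default_rng(_subseeds(seed, 1)[0])
    u = rng.normal(size=(200, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    axes = np.array([30.0, 25.0, 20.0])
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    pts = (u * axes) @ q.T + np.array([60.0, 55.0, 50.0])
    model = _sp.fit_ellipsoid(pts)
    axis_err = float(np.max(np.abs(model.semi_axes - axes) / axes))
    return {
        "accuracy_pct": 100.0 * accuracy,
        "n_cells": int(len(m)),
        "axis_max_error_pct": 100.0 * axis_err,
        "n_surface_points": len(pts),
    }


# ------------------------------------------------------------------ lineage


def _movie_anova_p(seed: int) -> tuple[float, int, int]:
    """(adjusted OUT-TE vs IN-ICM p, families checked, families agreeing)."""
    params = _sim.SimParams(seed=seed, reposition_prob=0.05)
    nuclei, tracks, truth = _sim.simulate_embryo_series(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = _sp.classify_nucleus_table(nuclei)
    forest = _lin.build_forest(tracks, nuclei)
    classes = _lin.classify_families(forest, pos)

    # families whose per-cell labels all match the ground truth must be
    # classified identically to the generated class
    m = pos.merge(truth.labels, on=["embryo_id", "cell_id", "frame"])
    m["label_ok"] = m.in_out == m.true_label
    fam_ok = m.groupby(["embryo_id", "family_id"]).label_ok.all()
    merged = classes.merge(truth.families, on=["embryo_id", "family_id"])
    merged = merged.set_index(["embryo_id", "family_id"]).join(
        fam_ok.rename("ok")
    )
    checked = merged[merged.ok]
    agree = int((checked.family_class == checked.true_class).sum())

    df = _q.correct_z_attenuation(nuclei, "ch1")
    df = _q.standardize_embryo(df, "ch1")
    traj = _lin.family_mean_trajectory(forest, df, "ch1_std", classes)
    gm = traj["family_grand_mean"].rename("gm").to_frame().join(
        traj["family_class"]
    )
    groups, labels = [], []
    for k in ("IN-ICM", "IN-TE+ICM", "OUT-TE", "OUT-TE+ICM"):
        v = gm.loc[gm.family_class == k, "gm"].dropna().values
        if len(v) >= 2:
            groups.append(v)
            labels.append(k)
    res = _st.anova_bonferroni(groups, labels)
    padj = {frozenset((a, b)): p for a, b, _, _, p in res.pairwise}
    p = padj.get(frozenset(("IN-ICM", "OUT-TE")), float("nan"))
    return p, int(len(checked)), agree


def family_class_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Fate-class agreement and reporter-difference detection over movies.

    Each replicate simulates 7 movies (16 -> up to 32 cells, repositioning
    probability 0.05), classifies positions and families with the full
    pipeline, and tests the OUT-TE vs IN-ICM mean standardized-reporter
    difference (Bonferroni-adjusted pairwise test of the one-way ANOVA).
    """
    checked = agreed = detected = 0
    for s in _subseeds(seed, n_seeds):
        p, n_chk, n_agree = _movie_anova_p(s)
        checked += n_chk
        agreed += n_agree
        detected += p < 0.05
    return {
        "noise_free_agreement_pct": 100.0 * agreed / checked,
        "n_families_checked": checked,
        "anova_detection_pct": 100.0 * detected / n_seeds,
        "n_seeds": n_seeds,
    }


# ------------------------------------------------------------- normalization


def normalization_invariants(seed: int) -> dict:
    """Standardization and z-correction invariants on simulated movies."""
    params = _sim.SimParams(seed=seed, n_embryos=5, n_frames=8)
    nuclei, _, _ = _sim.simulate_embryo_series(params)
    df = _q.correct_z_attenuation(nuclei, "ch1")
    df = _q.standardize_embryo(df, "ch1")
    g = df.groupby("embryo_id").ch1_std
    mean_max = float(g.mean().abs().max())
    sd_dev_max = float((g.std(ddof=1) - 1.0).abs().max())
    slope_max = 0.0
    for _, sub in df.groupby("embryo_id"):
        slope = np.polyfit(sub.z_um, np.log(sub.ch1_corr), 1)[0]
        slope_max = max(slope_max, abs(float(slope)))

    # exact inversion of the multiplicative decay at zero noise: with a
    # constant log-mean the observed signal is exactly exp(c - k z), so the
    # corrected values all equal exp(c - k * median z)
    channels = [_sim.ChannelModel(4.2, 4.2, 0.0, 0.0, 0.0)]
    clean = _sim.SimParams(
        seed=seed + 1, n_embryos=3, n_frames=6, channel_model=channels,
        centroid_noise_sd=0.0, reposition_prob=0.0,
    )
    nuclei0, _, _ = _sim.simulate_embryo_series(clean)
    corr = _q.correct_z_attenuation(nuclei0, "ch1")
    inv_err = 0.0
    for e, sub in corr.groupby("embryo_id"):
        zmed = np.median(sub.z_um)
        expected = np.exp(4.2 - clean.z_decay * zmed)
        inv_err = max(
            inv_err,
            float(np.max(np.abs(sub.ch1_corr - expected) / expected)),
        )
    return {
        "standardized_mean_max_abs": mean_max,
        "standardized_sd_max_abs_dev": sd_dev_max,
        "zslope_after_correction_max_abs": slope_max,
        "decay_inversion_max_rel_err": inv_err,
        "n_embryos": params.n_embryos,
    }


# --------------------------------------------------------------- correlation


def correlation_structure(seed: int, n_seeds: int = 100,
                          n_cells: int = 400) -> dict:
    """Multiple vs pairwise R² on cohorts with additively coupled channels."""
    coupling = _sim.CohortCoupling(a=1.0, b=1.0,
                                   noise_sd=math.sqrt(0.5) * 10.0)
    wins = 0
    mults, pairs = [], []
    for s in _subseeds(seed, n_seeds):
        params = _sim.SimParams(
            seed=s, n_embryos=10, n_cells_start=n_cells // 10,
            n_cells_end=n_cells // 10, n_frames=1, z_decay=0.0,
        )
        t = _sim.simulate_fixed_cohort(params, coupling)
        p1 = _st.pearson_r2(t.ch1, t.ch3).r2
        p2 = _st.pearson_r2(t.ch2, t.ch3).r2
        mr = _st.multiple_r2(t.ch3, t[["ch1", "ch2"]].values).r2
        wins += mr > max(p1, p2)
        mults.append(mr)
        pairs.append(max(p1, p2))
    return {
        "multiple_exceeds_pairwise_pct": 100.0 * wins / n_seeds,
        "mean_multiple_r2": float(np.mean(mults)),
        "mean_best_pairwise_r2": float(np.mean(pairs)),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }


# ------------------------------------------------------------------ scanning


def _sliding_window_oracle(seq: str, model: _reg.MotifModel,
                           thr_int: int) -> list[tuple]:
    """Independent rescoring of every window via a materialized window
    matrix (numpy sliding_window_view), both strands."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    w = model.width
    if len(idx) < w:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    hits = []
    for strand in ("+", "-"):
        ints = model.int_scores()
        if strand == "-":
            ints = ints[::-1, ::-1]
        # 5th column: windows containing N can never reach the threshold
        score_lut = np.concatenate(
            [ints, np.full((w, 1), -(1 << 40), dtype=np.int64)], axis=1
        )
        scores = score_lut[np.arange(w)[None, :], windows].sum(axis=1)
        for i in np.nonzero(scores >= thr_int)[0]:
            hits.append((int(i), int(i) + w, strand, int(scores[i])))
    return sorted(hits)


def scanner_exactness(seed: int, n_seqs: int = 1000,
                      seq_len: int = 10_000) -> dict:
    """Scanner vs window-matrix oracle; score-tail DP vs enumeration."""
    rng = np.random.default_rng(seed)
    model = _reg.rbpj_consensus_pwm()
    cal = _reg.calibrate_threshold(model, alpha=1e-3)
    mismatches = 0
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for _ in range(n_seqs):
        seq = bases[rng.integers(0, 4, seq_len)].tobytes().decode()
        ours = sorted(
            (h.start, h.end, h.strand, h.score_int)
            for h in _reg.scan_sequence(seq, model, cal)
        )
        mismatches += ours != _sliding_window_oracle(seq, model,
                                                     cal.threshold_int)

    # exact tail probabilities vs exhaustive enumeration, widths <= 8
    dp_err = 0.0
    for width in range(1, 9):
        m = rng.dirichlet(np.full(4, 0.8), size=width)
        pwm = _reg.MotifModel(matrix=m)
        with warnings.catch_warnings():
            # short motifs may not reach the requested tail; irrelevant here
            warnings.simplefilter("ignore")
            cal_w = _reg.calibrate_threshold(pwm, alpha=1e-3)
        ints = pwm.int_scores()
        scores = np.zeros(1, dtype=np.int64)
        for j in range(width):
            scores = (scores[:, None] + ints[j][None, :]).ravel()
        for s in np.unique(scores):
            tail = float((scores >= s).sum()) / 4**width
            dp_err = max(dp_err, abs(cal_w.tail_prob(int(s)) - tail))

    # the canonical binding site is found; its two-base mutation is not
    site_cal = _reg.calibrate_threshold(model, alpha=1e-4)
    site = "A" * 30 + "TGTGGGAAA" + "C" * 30
    mutant = "A" * 30 + "TGTCCGAAA" + "C" * 30
    site_hits = len(_reg.scan_sequence(site, model, site_cal))
    mutant_hits = len(_reg.scan_sequence(mutant, model, site_cal))
    return {
        "oracle_mismatch_count": int(mismatches),
        "n_sequences": n_seqs,
        "dp_tail_max_abs_err": dp_err,
        "site_hits": site_hits,
        "mutant_site_hits": mutant_hits,
    }


# ------------------------------------------------------------------- funnel


def funnel_correctness(seed: int, n_designs: int = 50) -> dict:
    """Planted funnel counts recovered exactly across random designs."""
    pwm = _reg.rbpj_consensus_pwm()
    exact = mono = 0
    example = None
    for s in _subseeds(seed, n_designs):
        rng = np.random.default_rng(s)
        n = int(rng.integers(2, 6))
        planted = []
        for i in range(n):
            if rng.random() < 0.75:
                planted.append(
                    _sim.PlantedMotif(
                        i, int(rng.integers(-9000, 9000)),
                        "+" if rng.random() < 0.5 else "-",
                        bool(rng.random() < 0.6),
                    )
                )
        params = _sim.GenomeFixtureParams(
            seed=s, genome_length=200_000, n_genes=n,
            planted_motifs=planted,
        )
        fx = _sim.simulate_genome_fixture(params, pwm)
        genes = [
            _reg.GenomicInterval(r.chrom, r.start, r.end, r.strand, r.name)
            for r in fx.genes.itertuples()
        ]
        peaks = [
            _reg.GenomicInterval(r.chrom, r.start, r.end, ".", r.name)
            for r in fx.peaks.itertuples()
        ]
        rep = _reg.candidate_filter_report(
            fx.deg, genes, {fx.chrom: fx.sequence}, pwm, peaks,
            half_width=fx.half_width, alpha=fx.alpha,
        )
        exact += rep.funnel == fx.expected_funnel
        mono += rep.n_deg >= rep.n_with_motif >= rep.n_in_open_chromatin
        if example is None:
            example = rep.funnel
    return {
        "exact_match_pct": 100.0 * exact / n_designs,
        "monotone_pct": 100.0 * mono / n_designs,
        "n_designs": n_designs,
        "example_funnel": example,
    }


# -------------------------------------------------------------- calibration


def statistical_calibration(seed: int, max_total: int = 40,
                            n_reps: int = 10_000) -> dict:
    """Fisher vs exact enumeration; t and chi-square type-I error rates."""
    # Fisher: every 2x2 table with total <= max_total against an
    # exact-integer enumeration oracle (numerator comparison, no floats)
    max_diff = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for r1 in range(n + 1):
            for c1 in range(n + 1):
                denom = math.comb(n, c1)
                support = range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                nums = {
                    a: math.comb(r1, a) * math.comb(n - r1, c1 - a)
                    for a in support
                }
                vals = sorted(nums.values())
                cum = np.cumsum(vals)
                for a, num_obs in nums.items():
                    table = [[a, r1 - a], [c1 - a, n - r1 - (c1 - a)]]
                    p_impl = _st.fisher_exact_2x2(table)
                    import bisect

                    k = bisect.bisect_right(vals, num_obs)
                    p_oracle = float(cum[k - 1]) / denom
                    max_diff = max(max_diff, abs(p_impl - p_oracle))
                    n_tables += 1

    rng = np.random.default_rng(seed)
    t_rej = 0
    for _ in range(n_reps):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        t_rej += _st.students_t(x, y).p_value < 0.05
    chi_rej = 0
    done = 0
    while done < n_reps:
        tab = np.vstack(
            [rng.multinomial(50, [0.5, 0.5]), rng.multinomial(50, [0.5, 0.5])]
        )
        if (tab.sum(axis=0) == 0).any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chi_rej += _st.chi_square_homogeneity(tab).p_value < 0.05
        done += 1
    return {
        "fisher_max_abs_diff": max_diff,
        "n_tables": n_tables,
        "t_type1_error": t_rej / n_reps,
        "chi2_type1_error": chi_rej / n_reps,
        "n_reps": n_reps,
    }
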