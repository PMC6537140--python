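"""Monte-Carlo validation studies run on the synthetic instrument.

Each study exercises the full pipeline (render -> segment -> TVB ->
image-wise fit -> statistics) under controlled ground truth and returns
the summary quantities used for validation.  Frame sizes and cell counts
are scaled below the instrument's full field where a study needs many
replicates; the statistical conditions (photon budgets, FOV counts per
strain, effect sizes) are preserved.
"""

from __future__ import annotations

import numpy as np

from .fitting import process_fov
from .plate_io import AcquisitionTemplate, default_template
from .segmentation import build_intensity_image, detect_foci_nth, mask_dead_cells
from .simulate import (
    DEFAULT_IRF,
    focus_amplitude_for_peak_snr,
    generate_reference_decay,
    random_scene,
    render_gated_stack,
)
from .stats import rank_sum_test

__all__ = [
    "small_template",
    "stochastic_recovery_study",
    "segmentation_quality_study",
    "detection_power_study",
]

#: Donor lifetime of unFRETed mTurquoise2 (ns), the negative-control truth.
DONOR_TAU_NS = 4.0


def small_template(frame_shape=(96, 96)) -> AcquisitionTemplate:
    """Default gating sequence on a reduced field, for replicate studies."""
    return default_template(frame_shape=frame_shape)


def _match_foci(true_rc: np.ndarray, centers, radius_px: float = 2.0):
    """Greedy one-to-one matching of detections to ground truth."""
    C = np.asarray(centers, dtype=float).reshape(-1, 2)
    matched = np.zeros(len(true_rc), dtype=bool)
    used = np.zeros(len(C), dtype=bool)
    for i, rc in enumerate(true_rc):
        if not len(C):
            break
        d = np.sqrt(((C - rc) ** 2).sum(axis=1))
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= radius_px:
            matched[i] = True
            used[j] = True
    return matched, used


def stochastic_recovery_study(
    tau_ns: float = 2.5,
    n_replicates: int = 100,
    seed: int = 0,
    irf=DEFAULT_IRF,
    frame_shape=(96, 96),
    n_cells: int = 2,
    focus_amplitude_dn: float = 2.5e4,
) -> dict:
    """Fit replicate noisy FOVs of known lifetime at a low photon budget.

    Scenes carry ~2-3 foci so the pooled FLIM signal sits near the 1.2e5 DN
    QC threshold; photobleaching is disabled to isolate photon noise.
    Returns the median bias and spread of QC-passing image-wise fits.
    """
    template = small_template(frame_shape)
    ref = generate_reference_decay(2.5, irf, template)
    taus, totals = [], []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        scene = random_scene(
            template,
            tau_ns,
            rng,
            n_cells=n_cells,
            focus_amplitude_dn=focus_amplitude_dn,
            bleach_rate=0.0,
            dead_cell_prob=0.0,
        )
        stack, _ = render_gated_stack(scene, template, irf)
        res = process_fov(stack, ref)
        totals.append(res.total_signal_dn)
        if res.qc_pass:
            taus.append(res.tau_fit_ns)
    taus = np.asarray(taus)
    return {
        "tau_true_ns": tau_ns,
        "n_qc_pass": int(taus.size),
        "n_replicates": n_replicates,
        "median_total_signal_dn": float(np.median(totals)),
        "median_bias_ps": float((np.median(taus) - tau_ns) * 1e3),
        "sigma_ps": float(np.std(taus) * 1e3),
    }


def segmentation_quality_study(
    peak_snr: float = 5.0,
    n_seeds: int = 20,
    seed: int = 0,
    irf=DEFAULT_IRF,
    match_radius_px: float = 2.0,
) -> dict:
    """Focus recall/precision and dead-cell exclusion at a fixed peak SNR.

    Full-size frames; every focus is rendered at the amplitude giving a
    worst-case (pixel-corner) peak SNR of ``peak_snr``, every FOV carries
    one injected dead cell.  Ground-truth foci swallowed by a dead cell's
    own footprint are not counted against recall (they are excluded by
    design).
    """
    template = default_template()
    amp = focus_amplitude_for_peak_snr(peak_snr, template, irf)
    recalls, precisions = [], []
    n_dead = n_dead_covered = 0
    focus_overlaps = 0
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        scene = random_scene(
            template,
            DONOR_TAU_NS,
            rng,
            focus_amplitude_dn=amp,
            amplitude_cv=0.0,
            dead_cell_prob=1.0,
        )
        stack, truth = render_gated_stack(scene, template, irf)
        intensity = build_intensity_image(stack)
        exclusion = mask_dead_cells(intensity)
        centers = detect_foci_nth(intensity, exclusion)
        true_rc = np.array([(f[0], f[1]) for f in truth["foci"]])
        keep = np.ones(len(true_rc), dtype=bool)
        for dr, dc, rad in truth["dead_cells"]:
            n_dead += 1
            n_dead_covered += bool(exclusion[int(dr), int(dc)])
            keep &= np.sqrt(((true_rc - (dr, dc)) ** 2).sum(axis=1)) > rad + 4
        true_rc = true_rc[keep]
        matched, used = _match_foci(true_rc, centers, match_radius_px)
        recalls.append(matched.mean() if len(true_rc) else 1.0)
        precisions.append(used.mean() if len(used) else 1.0)
        for r, c in centers:
            focus_overlaps += bool(exclusion[r, c])
    return {
        "peak_snr": peak_snr,
        "recall_median": float(np.median(recalls)),
        "precision_median": float(np.median(precisions)),
        "dead_cell_exclusion_rate": n_dead_covered / n_dead if n_dead else 1.0,
        "focus_center_overlap_count": focus_overlaps,
    }


def detection_power_study(
    delta_tau_ps: float = 250.0,
    n_plates: int = 100,
    n_fov_per_strain: int = 45,
    seed: int = 0,
    irf=DEFAULT_IRF,
    frame_shape=(96, 96),
    n_cells: int = 5,
    alpha_corrected: float = 0.05,
) -> dict:
    """Fraction of simulated plates calling a query-vs-control difference.

    Each plate: one donor-only control strain (tau = 4.0 ns) and one query
    strain whose donor lifetime is reduced by ``delta_tau_ps`` (FRET), each
    with ``n_fov_per_strain`` FOVs at the default photon budget; QC-passing
    image-wise lifetimes are compared with the two-sided rank-sum test at
    the (Bonferroni-corrected) level.  ``delta_tau_ps=0`` measures the
    type-I error rate.
    """
    template = small_template(frame_shape)
    ref = generate_reference_decay(2.5, irf, template)
    tau_query = DONOR_TAU_NS - delta_tau_ps * 1e-3

    def fov_tau(tau: float, rng) -> float:
        scene = random_scene(template, tau, rng, n_cells=n_cells, dead_cell_prob=0.0)
        stack, _ = render_gated_stack(scene, template, irf)
        res = process_fov(stack, ref)
        return res.tau_fit_ns if res.qc_pass else np.nan

    n_sig = 0
    for child in np.random.SeedSequence(seed).spawn(n_plates):
        rng = np.random.default_rng(child)
        ctrl = np.array([fov_tau(DONOR_TAU_NS, rng) for _ in range(n_fov_per_strain)])
        qry = np.array([fov_tau(tau_query, rng) for _ in range(n_fov_per_strain)])
        p = rank_sum_test(qry[np.isfinite(qry)], ctrl[np.isfinite(ctrl)])
        n_sig += p < alpha_corrected
    return {
        "delta_tau_ps": delta_tau_ps,
        "n_plates": n_plates,
        "n_fov_per_strain": n_fov_per_strain,
        "significant_fraction": n_sig / n_plates,
    }
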