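"""End-to-end workflow: simulate -> measure -> calibrate -> classify -> ecology.

This is the desk-scale analogue of the field workflow: polarized-light
frames yield per-coccolith mass and apparent length; a cross-instrument
calibration corrects the lengths; SEM-style tables yield the variety
percentages; per-sample aggregates (M_s, L_c, C_i, variety %) are then
correlated with the environment and ordinated by CCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import LengthCalibration, fit_length_correction
from .classify import TYPE_A, ClassificationPolicy, VarietyTable, classify_variety, \
    tabulate_varieties
from .imaging import ParticleMeasurement, measure_image, measure_sem
from .metrics import CalciteConstants, DEFAULT_CONSTANTS, SampleSummary, \
    calcification_index, normalized_mass
from .optics import OpticsConfig
from .render import place_on_grid, render_plm_image
from .shapes import CoccolithShape
from .stats import CCAResult, cca, spearman_matrix
from .transect import TransectConfig, generate_transect


def summarize_sample(
    particles: list[ParticleMeasurement],
    varieties: VarietyTable | None = None,
    model: LengthCalibration | None = None,
    constants: CalciteConstants = DEFAULT_CONSTANTS,
    station: int = 0,
    depth_m: float = 0.0,
    typeA_percent: float = float("nan"),
) -> SampleSummary:
    """Aggregate one sample's particle measurements.

    M_s is the mean mass over intact-and-isolated particles; L_c is the
    calibration-corrected mean apparent length; C_i = M_s / M_n follows.
    Raises if no particle survives the intact/isolated filter.
    """
    if model is None:
        model = LengthCalibration.published()
    kept = [p for p in particles if p.intact_isolated]
    if not kept:
        raise ValueError("no intact-isolated particles retained in sample")
    masses = np.array([p.mass for p in kept])
    lengths = np.array([p.apparent_length for p in kept])
    m_s = float(masses.mean())
    l_c = float(model.correct(float(lengths.mean())))
    m_n = normalized_mass(l_c, constants)
    return SampleSummary(
        station=station,
        depth_m=depth_m,
        mean_mass=m_s,
        mean_corrected_length=l_c,
        normalized_mass=m_n,
        calcification_index=calcification_index(m_s, l_c, constants),
        n_coccoliths=len(kept),
        typeA_percent=typeA_percent,
        variety_percent=dict(varieties.percentages) if varieties else {},
    )


@dataclass
class PipelineResult:
    summaries: pd.DataFrame  # per-sample M_s, L_c, M_n, C_i, variety %
    env: pd.DataFrame  # per-sample environment
    calibration: LengthCalibration
    morpho_env_correlations: pd.DataFrame  # Spearman battery
    cca: CCAResult


def run_pipeline(
    config: TransectConfig | None = None,
    optics: OpticsConfig | None = None,
    policy: ClassificationPolicy | None = None,
    constants: CalciteConstants = DEFAULT_CONSTANTS,
    coccoliths_per_frame: int = 16,
    max_frames_per_sample: int = 3,
    frame_shape: tuple[int, int] = (640, 640),
    n_calibration: int = 60,
    refit_calibration: bool = True,
) -> PipelineResult:
    """Run the whole synthetic study with one seed (carried by ``config``).

    Per sample, up to ``max_frames_per_sample`` frames of
    ``coccoliths_per_frame`` coccoliths are rendered and measured (a
    subsample of the generated assemblage — enough for stable means at
    desk scale); variety percentages use the SEM-style measurements of
    the full Type A assemblage.  The length calibration is refit from
    ``n_calibration`` coccoliths spread across samples (apparent length
    from the rendered image vs true DSL), or the published model is used
    when ``refit_calibration`` is false.
    """
    if config is None:
        config = TransectConfig()
    if optics is None:
        optics = OpticsConfig()
    if policy is None:
        policy = ClassificationPolicy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0CC0]))

    samples, env = generate_transect(config)
    if not samples:
        raise ValueError("transect generated no samples")

    rows = []
    calib_pairs: list[tuple[float, float]] = []
    for (station, depth), shapes in samples.items():
        type_a = [s for s in shapes if s.variety_label != "BC"]
        typeA_pct = 100.0 * len(type_a) / len(shapes) if shapes else float("nan")

        # SEM stage: classify the Type A assemblage from its measurements
        labels = [classify_variety(measure_sem(s), policy) for s in type_a]
        table = tabulate_varieties(labels) if labels else None

        # PLM stage: render and measure a subsample
        particles: list[ParticleMeasurement] = []
        n_frames = min(max_frames_per_sample,
                       max(1, len(shapes) // coccoliths_per_frame))
        for f in range(n_frames):
            lo = f * coccoliths_per_frame
            batch = shapes[lo:lo + coccoliths_per_frame]
            if not batch:
                break
            placements = place_on_grid(batch, optics, frame_shape, rng=rng)
            image, truth = render_plm_image(placements, optics, rng,
                                            frame_shape=frame_shape)
            measured = [p for p in measure_image(image) if p.intact_isolated]
            particles.extend(measured)
            # pair measured apparent lengths with true DSL by proximity
            if len(calib_pairs) < n_calibration:
                calib_pairs.extend(
                    _match_lengths(measured, placements, optics)
                )

        summary = summarize_sample(
            particles, table, LengthCalibration.published(), constants,
            station=station, depth_m=depth, typeA_percent=typeA_pct,
        )
        row = {
            "station": station, "depth_m": depth,
            "n": summary.n_coccoliths,
            "M_s_pg": summary.mean_mass,
            "apparent_mean_um": float(np.mean(
                [p.apparent_length for p in particles])),
            "typeA_percent": typeA_pct,
        }
        for v in TYPE_A:
            row[f"{v}_pct"] = summary.variety_percent.get(v, float("nan"))
        rows.append(row)

    summaries = pd.DataFrame(rows)

    model = (fit_length_correction(calib_pairs[:n_calibration])
             if refit_calibration and len(calib_pairs) >= 2
             else LengthCalibration.published())
    summaries["L_c_um"] = model.correct(summaries["apparent_mean_um"].to_numpy())
    summaries["M_n_pg"] = normalized_mass(summaries["L_c_um"].to_numpy(), constants)
    summaries["C_i"] = summaries["M_s_pg"] / summaries["M_n_pg"]

    env_vars = env.drop(columns=["station", "longitude_E", "depth_m"])
    morpho = summaries[["M_s_pg", "L_c_um", "C_i", "typeA_percent",
                        *(f"{v}_pct" for v in TYPE_A)]]
    correlations = spearman_matrix(morpho, env_vars.reset_index(drop=True))

    abundance = summaries[["typeA_percent", *(f"{v}_pct" for v in TYPE_A)]]
    cca_result = cca(abundance.fillna(0.0), env_vars.reset_index(drop=True))

    return PipelineResult(
        summaries=summaries,
        env=env,
        calibration=model,
        morpho_env_correlations=correlations,
        cca=cca_result,
    )


def _match_lengths(measured, placements, optics) -> list[tuple[float, float]]:
    """Pair each measured particle with the placed coccolith nearest its
    centroid, yielding (apparent_length, true DSL) calibration pairs."""
    pairs = []
    if not placements:
        return pairs
    centers = np.array([[p.y_um, p.x_um] for p in placements])
    for m in measured:
        cy, cx = m.centroid
        pos = np.array([cy * optics.pixel_size, cx * optics.pixel_size])
        i = int(np.argmin(((centers - pos) ** 2).sum(axis=1)))
        pairs.append((m.apparent_length,
                      placements[i].shape.distal_shield_length))
    return pairs
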