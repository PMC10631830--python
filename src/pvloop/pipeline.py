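"""End-to-end orchestration of the validation workflow.

Ties the modules together for one paired dataset (non-invasive loop from
volumes + brachial pressure; reference loop from the catheter recording)
and for a whole cohort (method agreement across the seven metrics). Every
step is a pure function of its inputs and the configured parameters, so
reruns are byte-identical.
"""

from __future__ import annotations

import logging

from .comparison import AgreementResult, PairedMetrics, compare_methods
from .config import Config
from .elastance import ElastanceCurve, read_elastance_csv
from .invasive import (
    average_beats,
    build_reference_loop,
    correct_offset,
    flag_ectopy,
    lowpass_filter,
    segment_beats,
)
from .metrics import METRIC_NAMES, PVMetrics, compute_all_metrics
from .noninvasive import BrachialBP, PVLoop, compute_noninvasive_loop
from .volumes import VolumeCurve

__all__ = [
    "noninvasive_metrics",
    "reference_loop_from_recording",
    "reference_metrics",
    "cohort_agreement",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _elastance_from_config(config: Config) -> ElastanceCurve | None:
    if config.elastance_path is None:
        return None
    return read_elastance_csv(config.elastance_path)


def noninvasive_metrics(
    vol: VolumeCurve,
    bp: BrachialBP,
    config: Config | None = None,
    edp: float | None = None,
) -> tuple[PVLoop, PVMetrics]:
    """Non-invasive loop and metric set for one dataset."""
    config = config or Config()
    loop = compute_noninvasive_loop(
        vol, bp,
        edp=config.edp_default if edp is None else edp,
        elastance=_elastance_from_config(config),
    )
    return loop, compute_all_metrics(loop, vol.heart_rate)


def reference_loop_from_recording(recording, vol: VolumeCurve,
                                  config: Config | None = None) -> PVLoop:
    """Reference loop: filter, offset-correct, segment, de-ectopy, average."""
    config = config or Config()
    rec = lowpass_filter(recording, cutoff=config.filter_cutoff_hz)
    rec = correct_offset(rec)
    beats = segment_beats(rec)
    beats = flag_ectopy(beats, rr_tolerance=config.rr_tolerance)
    avg = average_beats(rec, beats)
    logger.info("averaged %d beats (peak SD %.2f mmHg)",
                avg.n_beats_averaged, avg.peak_sd)
    return build_reference_loop(avg, vol)


def reference_metrics(recording, vol: VolumeCurve,
                      config: Config | None = None) -> tuple[PVLoop, PVMetrics]:
    """Reference loop and metric set for one dataset."""
    loop = reference_loop_from_recording(recording, vol, config)
    return loop, compute_all_metrics(loop, vol.heart_rate)


def cohort_agreement(datasets, config: Config | None = None
                     ) -> dict[str, AgreementResult]:
    """Run both pipelines on every dataset and compare all seven metrics.

    ``datasets`` is an iterable of objects with ``label``, ``volume_curve``,
    ``bp`` and ``recording`` attributes (e.g.
    :class:`~pvloop.synthetic.SyntheticDataset`).
    """
    labels, m_a, m_b = [], [], []
    for ds in datasets:
        _, ma = noninvasive_metrics(ds.volume_curve, ds.bp, config)
        _, mb = reference_metrics(ds.recording, ds.volume_curve, config)
        labels.append(ds.label)
        m_a.append(ma)
        m_b.append(mb)
    pairs = PairedMetrics(labels=labels, method_a=m_a, method_b=m_b)
    return {name: compare_methods(pairs, name) for name in METRIC_NAMES}


def run_pipeline(datasets, config: Config | None = None, seed: int | None = None
                 ) -> dict:
    """Full cohort report: per-metric agreement plus a provenance manifest."""
    from importlib.metadata import version

    agreement = cohort_agreement(datasets, config)
    try:
        pkg_version = version("pvloop")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    return {
        "schema_version": 1,
        "pvloop_version": pkg_version,
        "seed": seed,
        "n_datasets": len(list(datasets)),
        "agreement": {k: v.as_dict() for k, v in agreement.items()},
    }
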