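"""Cycle-to-threshold (CTOT) censored representation of qPCR data.

qPCR reports the cycle number (Ct) at which fluorescence crosses the
detection threshold.  Assays stop at a maximum cycle (the Ct *cutoff*,
typically 32 or 40); a recorded Ct at or above the cutoff means the
threshold was not certainly reached — the observation is informative but
incomplete, exactly like an administratively censored event time.

Normalization subtracts a reference (normalizer) Ct from the target Ct.
Because the cutoff applies on the raw cycle axis, subtracting a
sample-specific normalizer moves the censoring point to the
sample-specific value ``cutoff - normalizer_ct`` on the normalized axis.
This module performs that transform and carries the censoring
information along explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataValidationError

__all__ = ["CensoredSample", "TransformSummary", "combine_references", "censor_transform"]


@dataclass(frozen=True)
class CensoredSample:
    """One sample on the normalized cycle-to-threshold scale.

    Attributes
    ----------
    time
        Normalized cycle-to-threshold value ``min(raw_ct, cutoff) -
        normalizer_ct`` (a ΔCt; may legitimately be negative).
    event
        True iff the fluorescence threshold was certainly reached before
        the cutoff, i.e. ``raw_ct < cutoff`` (strict: a Ct that meets the
        cutoff is treated as uncertain).
    predictor
        The binary group indicator (0/1) or the numeric covariate.
    raw_ct, normalizer_ct
        The untransformed inputs, kept for traceability.
    """

    time: float
    event: bool
    predictor: float
    raw_ct: float
    normalizer_ct: float


@dataclass(frozen=True)
class TransformSummary:
    n: int
    n_events: int
    n_censored: int
    n_dropped: int


def combine_references(reference_cts: Sequence[float]) -> float:
    """Combine k reference Ct values into a single normalizer Ct.

    Ct values live on a log2 scale of input quantity, so the arithmetic
    mean of Ct values corresponds to the geometric mean of the
    linear-scale quantities — the conventional multi-reference
    normalizer.
    """
    cts = [float(c) for c in reference_cts]
    if len(cts) == 0:
        raise DataValidationError("at least one reference Ct value is required")
    if not all(math.isfinite(c) for c in cts):
        raise DataValidationError("reference Ct values must be finite")
    return float(np.mean(cts))


def censor_transform(frame, normalizer_policy: str = "error"):
    """Map an analysis frame to its censored CTOT representation.

    Event status is decided on the raw Ct scale (``raw_ct < cutoff``),
    then the observation — or, for censored samples, the censoring point
    itself — is shifted by the sample's normalizer Ct.

    Parameters
    ----------
    frame : ctot.dataio.AnalysisFrame
        Validated frame in two-group or regression mode.
    normalizer_policy : {"error", "drop"}
        A normalizer Ct at or above the cutoff makes normalization
        undefined.  ``"error"`` (default) raises naming the sample;
        ``"drop"`` removes the sample with a warning.

    Returns
    -------
    (samples, summary) : (list[CensoredSample], TransformSummary)
    """
    if normalizer_policy not in ("error", "drop"):
        raise ValueError("normalizer_policy must be 'error' or 'drop'")
    cutoff = float(frame.cutoff)
    predictors = frame.predictor_values()
    samples: list[CensoredSample] = []
    n_dropped = 0
    for i in range(len(frame.ct)):
        ct = float(frame.ct[i])
        norm = float(frame.normalizer_ct[i])
        if norm >= cutoff:
            sid = frame.sample_id[i] if frame.sample_id is not None else f"row {i + 1}"
            if normalizer_policy == "error":
                raise DataValidationError(
                    f"normalizer Ct {norm} for sample {sid!r} meets or exceeds the "
                    f"cutoff {cutoff}; normalization is undefined for this sample"
                )
            warnings.warn(
                f"dropping sample {sid!r}: normalizer Ct {norm} >= cutoff {cutoff}",
                stacklevel=2,
            )
            n_dropped += 1
            continue
        event = ct < cutoff
        time = (ct if event else cutoff) - norm
        samples.append(
            CensoredSample(
                time=time,
                event=event,
                predictor=float(predictors[i]),
                raw_ct=ct,
                normalizer_ct=norm,
            )
        )
    n_events = sum(s.event for s in samples)
    summary = TransformSummary(
        n=len(samples),
        n_events=n_events,
        n_censored=len(samples) - n_events,
        n_dropped=n_dropped,
    )
    return samples, summary
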