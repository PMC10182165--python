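"""Fold-safe standardization, padding/masking, and delta features.

Standardization statistics pool all scan-rows of the fitting patients (each
scan is one observation) and use the population (1/N) standard-deviation
denominator; the fitted transform is then *kept* and applied unchanged to
held-out patients, never re-fitted — the `fitted_on` record makes that
auditable in cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, PatientSeries, StreamSchema
from .errors import DegenerateFeatureError, SchemaError, ValidationError

PAD_VALUE = 0.0  # standardized mean; masked steps are never read by the model


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale over the flat feature vector (length sum d_k),
    plus the id set it was fitted on for leakage auditing."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise SchemaError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd <= 0):
            raise DegenerateFeatureError("all sd entries must be strictly positive")


def fit_standardizer(cohort: Cohort, patient_subset) -> StandardizationParams:
    """Compute per-feature mean and population sd over all scans of the subset.

    Raises :class:`DegenerateFeatureError` naming the first constant feature —
    a feature with a single distinct value cannot be scaled.
    """
    subset = set(patient_subset)
    if not subset:
        raise ValidationError("patient_subset must be non-empty")
    rows = [p.flat_matrix() for p in cohort.patients if p.patient_id in subset]
    if len(rows) != len(subset):
        found = {p.patient_id for p in cohort.patients} & subset
        raise ValidationError(f"unknown patient ids in subset: {sorted(subset - found)}")
    stacked = np.concatenate(rows, axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = cohort.schema.flat_feature_names
        raise DegenerateFeatureError(
            f"constant feature(s) on fitting subset: {[names[i] for i in bad]}"
        )
    return StandardizationParams(mean=mean, sd=sd, fitted_on=frozenset(subset))


def _transform_patient(p: PatientSeries, params: StandardizationParams,
                       schema: StreamSchema) -> PatientSeries:
    flat = (p.flat_matrix() - params.mean) / params.sd
    streams, col = [], 0
    for w in schema.widths:
        streams.append(flat[:, col : col + w].copy())
        col += w
    return PatientSeries(patient_id=p.patient_id, label=p.label,
                         times=p.times.copy(), streams=streams)


def apply_standardizer(params: StandardizationParams, data):
    """Return a standardized copy of a :class:`Cohort` or :class:`PatientSeries`;
    the input is untouched."""
    if isinstance(data, Cohort):
        if params.mean.size != data.schema.total_width:
            raise SchemaError(
                f"params cover {params.mean.size} features, schema has "
                f"{data.schema.total_width}"
            )
        return Cohort(data.schema,
                      [_transform_patient(p, params, data.schema) for p in data.patients])
    if isinstance(data, PatientSeries):
        total = sum(s.shape[1] for s in data.streams)
        if params.mean.size != total:
            raise SchemaError(
                f"params cover {params.mean.size} features, patient has {total}"
            )
        widths = tuple(s.shape[1] for s in data.streams)
        schema = StreamSchema(
            stream_names=tuple(f"s{k}" for k in range(len(widths))), widths=widths
        )
        return _transform_patient(data, params, schema)
    raise TypeError(f"expected Cohort or PatientSeries, got {type(data).__name__}")


@dataclass
class PaddedBatch:
    """Post-padded, masked tensors for a list of patients.

    ``streams[k]`` has shape N x T_max x d_k; ``mask`` is N x T_max with
    prefix-ones rows (mask[i, j] = 1 iff j < T_i); padded positions hold
    :data:`PAD_VALUE` and must never influence model output.
    """

    streams: list[np.ndarray]
    mask: np.ndarray
    lengths: np.ndarray
    patient_ids: list[str]
    labels: np.ndarray


def pad_and_mask(patients: list[PatientSeries], schema: StreamSchema,
                 t_max: int | None = None) -> PaddedBatch:
    """Stack variable-length series into padded arrays with an observation mask.

    ``t_max`` may be given to pad beyond the longest series (used by the
    padding-invariance checks); it defaults to max T_i.
    """
    if not patients:
        raise ValidationError("pad_and_mask needs a non-empty patient list")
    lengths = np.array([p.n_visits for p in patients], dtype=int)
    if t_max is None:
        t_max = int(lengths.max())
    elif t_max < lengths.max():
        raise ValidationError(f"t_max={t_max} < longest series {lengths.max()}")
    n = len(patients)
    streams = []
    for k, d_k in enumerate(schema.widths):
        arr = np.full((n, t_max, d_k), PAD_VALUE, dtype=float)
        for i, p in enumerate(patients):
            if p.streams[k].shape[1] != d_k:
                raise SchemaError(
                    f"patient {p.patient_id}: stream {k} width "
                    f"{p.streams[k].shape[1]} != schema {d_k}"
                )
            arr[i, : lengths[i]] = p.streams[k]
        streams.append(arr)
    mask = (np.arange(t_max)[None, :] < lengths[:, None]).astype(float)
    return PaddedBatch(
        streams=streams,
        mask=mask,
        lengths=lengths,
        patient_ids=[p.patient_id for p in patients],
        labels=np.array([p.label for p in patients], dtype=int),
    )


def delta_features(patient: PatientSeries) -> np.ndarray:
    """Last-visit minus first-visit flat feature vector (the delta-radiomics
    summary: change in each feature between final and baseline scans)."""
    if patient.n_visits < 2:
        raise ValidationError(
            f"patient {patient.patient_id}: delta features need T_i >= 2, "
            f"got {patient.n_visits}"
        )
    flat = patient.flat_matrix()
    return flat[-1] - flat[0]
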