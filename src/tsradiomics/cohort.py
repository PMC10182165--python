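"""Domain containers and the delimited-text interchange format.

A cohort is a set of patients; each patient carries an ordered series of
visits (strictly increasing time offsets, in months from the baseline scan)
and, per visit, feature vectors grouped into K named streams (e.g.
T2WI-derived radiomics, ADC-derived radiomics, PSA density). Only the visit
*order* is consumed by the downstream sequence model; the real-valued time
offsets are carried for provenance and realism of the written files.

Interchange format (comma-separated, header row, UTF-8):

* ``features.csv`` — columns ``patient_id, visit_index, time_offset`` followed
  by every feature column in schema order (stream 1 columns, then stream 2, ...).
* ``labels.csv`` — columns ``patient_id, label`` with label in {0, 1}
  (1 = progressor, 0 = non-progressor).

Missing cells are an ingestion error: the modelling pipeline assumes complete
series (features robust at all time points), and imputation would be
unvalidated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DataError, MissingDataError, SchemaError

META_COLUMNS = ("patient_id", "visit_index", "time_offset")


@dataclass(frozen=True)
class StreamSchema:
    """Names, widths and column labels of the K parallel feature streams.

    Parameters
    ----------
    stream_names : ordered stream labels, e.g. ``("t2w", "adc", "psad")``.
    widths : per-stream column counts d_k.
    feature_names : per-stream ordered column labels; auto-generated as
        ``"<stream>_f<j>"`` when omitted.
    """

    stream_names: tuple[str, ...]
    widths: tuple[int, ...]
    feature_names: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.stream_names)
        widths = tuple(int(w) for w in self.widths)
        if len(names) != len(widths):
            raise SchemaError("stream_names and widths must have equal length")
        if len(names) < 1:
            raise SchemaError("schema needs at least one stream (K >= 1)")
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate stream names: {names}")
        if any(w < 1 for w in widths):
            raise SchemaError(f"every stream width d_k must be >= 1, got {widths}")
        feats = tuple(tuple(f) for f in self.feature_names)
        if not feats:
            feats = tuple(
                tuple(f"{s}_f{j}" for j in range(w)) for s, w in zip(names, widths)
            )
        if tuple(len(f) for f in feats) != widths:
            raise SchemaError("feature_names lengths must match widths")
        for s, f in zip(names, feats):
            if len(set(f)) != len(f):
                raise SchemaError(f"duplicate feature names within stream {s!r}")
        object.__setattr__(self, "stream_names", names)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "feature_names", feats)

    @property
    def n_streams(self) -> int:
        return len(self.stream_names)

    @property
    def total_width(self) -> int:
        return sum(self.widths)

    @property
    def flat_feature_names(self) -> tuple[str, ...]:
        return tuple(f for stream in self.feature_names for f in stream)

    @classmethod
    def default(cls) -> "StreamSchema":
        """The study layout: K=3 streams of widths 17 (T2WI), 27 (ADC), 1 (PSAd)."""
        return cls(stream_names=("t2w", "adc", "psad"), widths=(17, 27, 1))


@dataclass
class PatientSeries:
    """One patient's ordered visit series.

    ``streams[k]`` is a T_i x d_k matrix of the observed feature values
    x_ijk; ``times`` holds the strictly increasing offsets t_1..t_Ti in
    months from baseline; ``label`` is the binary outcome (1 = progressor).
    """

    patient_id: str
    label: int
    times: np.ndarray
    streams: list[np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.streams = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.streams]
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label!r} for {self.patient_id}")
        if self.times.ndim != 1 or self.times.size < 1:
            raise DataError(f"patient {self.patient_id}: needs at least one visit")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(
                f"patient {self.patient_id}: time offsets must be strictly increasing"
            )
        t = self.times.size
        for k, s in enumerate(self.streams):
            if s.shape[0] != t:
                raise SchemaError(
                    f"patient {self.patient_id}: stream {k} has {s.shape[0]} rows, "
                    f"expected T_i={t}"
                )
            if not np.isfinite(s).all():
                raise MissingDataError(
                    f"patient {self.patient_id}: non-finite value in stream {k}"
                )

    @property
    def n_visits(self) -> int:
        return int(self.times.size)

    def flat_matrix(self) -> np.ndarray:
        """T_i x (sum d_k) matrix with streams concatenated column-wise."""
        return np.concatenate(self.streams, axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.label == other.label
            and np.array_equal(self.times, other.times)
            and len(self.streams) == len(other.streams)
            and all(np.array_equal(a, b) for a, b in zip(self.streams, other.streams))
        )


@dataclass
class Cohort:
    """A schema plus a list of patients conforming to it."""

    schema: StreamSchema
    patients: list[PatientSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate patient ids: {dupes}")
        for p in self.patients:
            if tuple(s.shape[1] for s in p.streams) != self.schema.widths:
                raise SchemaError(
                    f"patient {p.patient_id}: stream widths "
                    f"{tuple(s.shape[1] for s in p.streams)} != schema {self.schema.widths}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.schema == other.schema
            and len(self.patients) == len(other.patients)
            and all(a == b for a, b in zip(self.patients, other.patients))
        )

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)

    @property
    def n_scans(self) -> int:
        return sum(p.n_visits for p in self.patients)

    def subset(self, ids: Iterable[str]) -> "Cohort":
        wanted = set(ids)
        missing = wanted - set(self.patient_ids)
        if missing:
            raise ConsistencyError(f"unknown patient ids: {sorted(missing)}")
        return Cohort(self.schema, [p for p in self.patients if p.patient_id in wanted])


def _split_streams(flat: np.ndarray, schema: StreamSchema) -> list[np.ndarray]:
    out, col = [], 0
    for w in schema.widths:
        out.append(np.ascontiguousarray(flat[:, col : col + w]))
        col += w
    return out


def read_cohort(features_path, labels_path, schema: StreamSchema) -> Cohort:
    """Read ``features.csv`` + ``labels.csv`` into a :class:`Cohort`.

    Visits are sorted by ``time_offset`` per patient; the 0-based
    ``visit_index`` column must agree with that ordering (disagreement is a
    data error rather than silently re-sorted metadata). Row order in the file
    never affects the result.
    """
    # round_trip parsing: written repr-floats must reproduce float64 exactly
    feat = pd.read_csv(features_path, dtype={"patient_id": str},
                       float_precision="round_trip")
    lab = pd.read_csv(labels_path, dtype={"patient_id": str})

    expected = list(META_COLUMNS) + list(schema.flat_feature_names)
    missing = [c for c in expected if c not in feat.columns]
    extra = [c for c in feat.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"features table column mismatch: missing={missing}, unexpected={extra}"
        )
    if list(lab.columns) != ["patient_id", "label"]:
        raise SchemaError(
            f"labels table must have columns ['patient_id', 'label'], got {list(lab.columns)}"
        )
    if feat[expected].isna().any().any():
        bad = [c for c in expected if feat[c].isna().any()]
        raise MissingDataError(f"empty cells in features columns {bad}")
    if lab.isna().any().any():
        raise MissingDataError("empty cells in labels table")
    if lab["patient_id"].duplicated().any():
        raise DataError("duplicate patient_id in labels table")
    bad_labels = set(lab["label"].unique()) - {0, 1}
    if bad_labels:
        raise DataError(f"labels must be 0/1, found {sorted(bad_labels)}")

    feat_ids = set(feat["patient_id"])
    lab_ids = set(lab["patient_id"])
    if feat_ids - lab_ids:
        raise ConsistencyError(f"patients without a label: {sorted(feat_ids - lab_ids)}")
    if lab_ids - feat_ids:
        raise ConsistencyError(f"labels without visits: {sorted(lab_ids - feat_ids)}")

    label_of = dict(zip(lab["patient_id"], lab["label"].astype(int)))
    patients = []
    # groupby(sort=True) gives a deterministic, row-order-independent patient order
    for pid, grp in feat.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_offset", kind="mergesort")
        times = grp["time_offset"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DataError(f"patient {pid}: duplicate or non-monotone time offsets")
        vidx = grp["visit_index"].to_numpy()
        if not np.array_equal(vidx, np.arange(len(grp))):
            raise DataError(
                f"patient {pid}: visit_index must be 0..T_i-1 in time order, got {vidx.tolist()}"
            )
        flat = grp[list(schema.flat_feature_names)].to_numpy(dtype=float)
        patients.append(
            PatientSeries(
                patient_id=str(pid),
                label=label_of[str(pid)],
                times=times,
                streams=_split_streams(flat, schema),
            )
        )
    return Cohort(schema=schema, patients=patients)


def write_cohort(cohort: Cohort, features_path, labels_path) -> None:
    """Write a cohort to the interchange format, round-trippable to full
    float64 precision by :func:`read_cohort`."""
    cols = list(META_COLUMNS) + list(cohort.schema.flat_feature_names)
    rows = []
    for p in cohort.patients:
        flat = p.flat_matrix()
        for j in range(p.n_visits):
            rows.append([p.patient_id, j, p.times[j], *flat[j]])
    feat = pd.DataFrame(rows, columns=cols)
    lab = pd.DataFrame(
        {"patient_id": cohort.patient_ids, "label": cohort.labels}
    )
    # repr-based float formatting round-trips float64 exactly
    feat.to_csv(features_path, index=False, float_format=None)
    lab.to_csv(labels_path, index=False)
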