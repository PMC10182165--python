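"""Shared fixtures: tiny hand-built cohorts and an independent scalar-loop
LSTM oracle used to pin the vectorised forward pass to the gate equations."""

from __future__ import annotations

import numpy as np
import pytest

from tsradiomics.cohort import Cohort, PatientSeries, StreamSchema
from tsradiomics.simulate import SimulationConfig, generate_cohort


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def oracle_patient_probability(patient: PatientSeries, params, tied: bool = False) -> float:
    """Literal, scalar-loop evaluation of the multistream LSTM for one
    patient: every gate equation written out with explicit index sums,
    iterating only over the T_i observed visits (no padding involved).
    Intentionally independent of the package's vectorised forward pass."""
    h_parts = []
    for k in range(params.schema.n_streams):
        d_k = params.schema.widths[k]
        h_k = params.hidden[k]
        w = {g: np.asarray(params.kernel(k, g)) for g in ("i", "f", "o", "c")}
        u = {g: np.asarray(params.recurrent(k, g)) for g in ("i", "f", "o", "c")}
        b = {g: np.asarray(params.bias(k, g)) for g in ("i", "f", "o", "c")}
        u_input = u["f"] if tied else u["i"]
        h = [0.0] * h_k
        c = [0.0] * h_k
        x_seq = patient.streams[k]
        for j in range(patient.n_visits):
            h_new, c_new = [0.0] * h_k, [0.0] * h_k
            for unit in range(h_k):
                zi = b["i"][unit]
                zf = b["f"][unit]
                zo = b["o"][unit]
                zc = b["c"][unit]
                for v in range(h_k):
                    zi += h[v] * u_input[v, unit]
                    zf += h[v] * u["f"][v, unit]
                    zo += h[v] * u["o"][v, unit]
                    zc += h[v] * u["c"][v, unit]
                for d in range(d_k):
                    zi += x_seq[j, d] * w["i"][d, unit]
                    zf += x_seq[j, d] * w["f"][d, unit]
                    zo += x_seq[j, d] * w["o"][d, unit]
                    zc += x_seq[j, d] * w["c"][d, unit]
                gate_i = sigmoid(zi)
                gate_f = sigmoid(zf)
                gate_o = sigmoid(zo)
                cand = np.tanh(zc)
                c_new[unit] = gate_f * c[unit] + gate_i * cand
                h_new[unit] = gate_o * np.tanh(c_new[unit])
            h, c = h_new, c_new
        h_parts.extend(h)
    logit = params.head_b
    for idx, hv in enumerate(h_parts):
        logit += hv * params.head_w[idx]
    return sigmoid(logit)


def random_patient(rng: np.random.Generator, pid: str, label: int,
                   schema: StreamSchema, t_i: int) -> PatientSeries:
    times = np.cumsum(rng.uniform(1.0, 6.0, size=t_i))
    return PatientSeries(
        patient_id=pid, label=label, times=times,
        streams=[rng.standard_normal((t_i, w)) for w in schema.widths],
    )


def random_cohort(rng: np.random.Generator, schema: StreamSchema, n: int,
                  t_range=(2, 5)) -> Cohort:
    patients = [
        random_patient(rng, f"p{i}", int(i % 2), schema,
                       int(rng.integers(t_range[0], t_range[1] + 1)))
        for i in range(n)
    ]
    return Cohort(schema, patients)


@pytest.fixture(scope="session")
def tiny_schema() -> StreamSchema:
    return StreamSchema(stream_names=("a", "b"), widths=(2, 1))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_schema) -> Cohort:
    rng = np.random.default_rng(123)
    return random_cohort(rng, tiny_schema, n=6, t_range=(3, 5))


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """Default synthetic cohort: 76 patients, 28 progressors, streams 17/27/1."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_drift_cohort() -> Cohort:
    """20-patient cohort with a clear class drift, cheap enough for LOOCV."""
    return generate_cohort(
        SimulationConfig(n_patients=20, n_progressors=8, drift_effect=1.0,
                         baseline_shift=0.0, seed=5)
    )
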