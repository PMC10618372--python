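"""Readers/writers for the package's interchange formats, plus run manifests.

Everything is plain structured text: event tables and traces as TSV,
kinetic schemes / dwell mixtures / neuron configurations as JSON.  Long
traces may alternatively be stored as a simple binary block (float32
little-endian) preceded by a one-line JSON text header.  Every pipeline
output can be traced back to a :class:`RunManifest` recording the command,
configuration snapshot, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .markov_core import KineticScheme, DwellMixture
from .idealization import EventTable, CLASS_NAMES
from .synthetic_data import CurrentTrace
from .neuron_sim import NeuronConfig, SweepResult

__all__ = [
    "RunManifest",
    "read_event_table", "write_event_table",
    "read_scheme", "write_scheme",
    "read_mixture", "write_mixture",
    "read_neuron_config", "write_neuron_config",
    "read_trace", "write_trace",
    "write_sweep_result", "read_sweep_result",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed interchange file."""


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_event_table(table: EventTable, path) -> None:
    df = table.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# dead_time_ms={table.dead_time_ms}\n")
        if table.sampling_rate_hz:
            fh.write(f"# sampling_rate_hz={table.sampling_rate_hz}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_event_table(path) -> EventTable:
    """Read an event-table TSV, validating schema and strict alternation."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        n_header = 0
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
            n_header += 1
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    required = {"start_ms", "duration_ms", "class"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if len(df) == 0:
        return EventTable(np.empty(0), np.empty(0), np.empty(0, dtype=np.uint8),
                          dead_time_ms=meta.get("dead_time_ms", 0.0),
                          sampling_rate_hz=meta.get("sampling_rate_hz"))
    bad = ~df["class"].isin(CLASS_NAMES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: line {row + n_header + 2}: unknown class {df['class'].iloc[row]!r}")
    cls = np.array([CLASS_NAMES.index(c) for c in df["class"]], dtype=np.uint8)
    same = np.flatnonzero(cls[1:] == cls[:-1])
    if same.size:
        raise FormatError(f"{path}: line {int(same[0]) + n_header + 3}: classes do not alternate")
    start = df["start_ms"].to_numpy(float)
    dur = df["duration_ms"].to_numpy(float)
    gaps = start[1:] - (start[:-1] + dur[:-1])
    if len(start) > 1 and np.max(np.abs(gaps)) > 1e-4 * max(1.0, float(dur.max())):
        row = int(np.argmax(np.abs(gaps)))
        raise FormatError(f"{path}: line {row + n_header + 3}: events overlap or leave a gap")
    # rebuild exactly-contiguous starts (text round-off tolerated on read)
    table = EventTable.from_durations(cls, dur, t0=float(start[0]),
                                      dead_time_ms=meta.get("dead_time_ms", 0.0),
                                      sampling_rate_hz=meta.get("sampling_rate_hz"))
    return table


# ---------------------------------------------------------------------------
# schemes and mixtures
# ---------------------------------------------------------------------------

def write_scheme(scheme: KineticScheme, path) -> None:
    n = scheme.n_states
    rates = [
        [scheme.state_ids[i], scheme.state_ids[j], scheme.rates[i, j]]
        for i in range(n) for j in range(n)
        if i != j and scheme.rates[i, j] > 0
    ]
    doc = {
        "states": list(scheme.state_ids),
        "classes": list(scheme.class_of_state),
        "rates_per_ms": rates,
        "unitary_conductance_pS": scheme.unitary_conductance,
        "reversal_potential_mV": scheme.reversal_potential,
        "reference_temperature_C": scheme.reference_temperature,
        "q10_forward": scheme.q10_forward,
        "forward_transitions": sorted(list(t) for t in scheme.forward_transitions),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_scheme(path) -> KineticScheme:
    doc = json.loads(Path(path).read_text())
    try:
        states = [str(s) for s in doc["states"]]
        idx = {s: i for i, s in enumerate(states)}
        Q = np.zeros((len(states), len(states)))
        for a, b, r in doc["rates_per_ms"]:
            Q[idx[str(a)], idx[str(b)]] = float(r)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return KineticScheme(
            state_ids=tuple(states),
            class_of_state=tuple(doc["classes"]),
            rates=Q,
            unitary_conductance=float(doc["unitary_conductance_pS"]),
            reversal_potential=float(doc["reversal_potential_mV"]),
            reference_temperature=float(doc["reference_temperature_C"]),
            q10_forward=float(doc.get("q10_forward", 1.0)),
            forward_transitions=frozenset(tuple(t) for t in doc.get("forward_transitions", [])),
        )
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: malformed scheme file ({e})") from e


def write_mixture(mix: DwellMixture, path) -> None:
    doc = {"class": mix.class_label, "taus_ms": list(mix.taus),
           "areas": list(mix.areas), "temperature_C": mix.temperature}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_mixture(path) -> DwellMixture:
    doc = json.loads(Path(path).read_text())
    try:
        return DwellMixture(doc["class"], tuple(doc["taus_ms"]), tuple(doc["areas"]),
                            temperature=float(doc.get("temperature_C", 22.0)))
    except (KeyError, TypeError, ValueError) as e:
        raise FormatError(f"{path}: malformed mixture file ({e})") from e


# ---------------------------------------------------------------------------
# neuron configuration
# ---------------------------------------------------------------------------

def write_neuron_config(config: NeuronConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=1))


def read_neuron_config(path) -> NeuronConfig:
    doc = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(NeuronConfig)}
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"{path}: unknown config fields {sorted(unknown)}")
    try:
        return NeuronConfig(**doc)
    except (TypeError, ValueError) as e:
        raise FormatError(f"{path}: invalid neuron config ({e})") from e


# ---------------------------------------------------------------------------
# current traces
# ---------------------------------------------------------------------------

def write_trace(trace: CurrentTrace, path, fmt: str = "tsv") -> None:
    """Write a trace as two-column TSV or as float32 binary with text header."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# {json.dumps({'sampling_rate_hz': trace.sampling_rate, **trace.metadata})}\n")
            fh.write("time_s\tcurrent_pA\n")
            np.savetxt(fh, np.column_stack([trace.times_s, trace.samples]),
                       fmt="%.6f\t%.5f")
    elif fmt == "bin":
        header = json.dumps({"sampling_rate_hz": trace.sampling_rate,
                             "n_samples": trace.samples.size,
                             "dtype": "float32-le", **trace.metadata})
        with open(path, "wb") as fh:
            fh.write(header.encode() + b"\n")
            fh.write(trace.samples.astype("<f4").tobytes())
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(path) -> CurrentTrace:
    path = Path(path)
    with open(path, "rb") as fh:
        first = fh.readline()
        rest = fh.read()
    try:
        meta = json.loads(first.decode().lstrip("# ").strip())
    except (UnicodeDecodeError, json.JSONDecodeError) as e:
        raise FormatError(f"{path}: missing/invalid trace header") from e
    fs = float(meta.pop("sampling_rate_hz"))
    if meta.get("dtype") == "float32-le":
        n = int(meta.pop("n_samples"))
        meta.pop("dtype")
        samples = np.frombuffer(rest[:4 * n], dtype="<f4").astype(float)
    else:
        arr = np.loadtxt(rest.decode().splitlines(), skiprows=1)
        samples = np.atleast_2d(arr)[:, 1]
    return CurrentTrace(samples=samples, sampling_rate=fs, metadata=meta)


# ---------------------------------------------------------------------------
# sweep results and manifests
# ---------------------------------------------------------------------------

def write_sweep_result(sweep: SweepResult, path) -> None:
    df = sweep.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# config_hash={sweep.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_sweep_result(path) -> SweepResult:
    with open(path) as fh:
        first = fh.readline()
        cfg_hash = first.partition("=")[2].strip() if first.startswith("#") else ""
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    return SweepResult(records=tuple(df.to_dict("records")), config_hash=cfg_hash)


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    seed: int | None
    config: dict
    inputs: list
    outputs: list
    package_version: str
    created_utc: str = ""

    @classmethod
    def create(cls, command, seed, config, inputs, outputs):
        from . import __version__

        return cls(command=command, seed=seed, config=config,
                   inputs=[str(p) for p in inputs], outputs=[str(p) for p in outputs],
                   package_version=__version__,
                   created_utc=datetime.datetime.now(datetime.timezone.utc).isoformat())


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
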