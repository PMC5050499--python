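"""File formats: event tables (QuB DWT-style and CSV), traces, scheme
configs.

All durations are serialized in milliseconds to six decimal places; rates
in s^-1.  The DWT dialect mirrors the tab-separated class-index/duration
lines of QuB dwell files with a segment header; the CSV dialect adds state
names and per-event amplitudes.  Trace files are a self-describing text
header followed by one sample per line ('text') or a JSON sidecar plus raw
little-endian float32 samples ('raw') for long recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .schemes import GatingScheme, build_scheme
from .synth import IdealizedRecord, Trace

_CLASS_INDEX = {"CLOSED": 0, "BLOCKED": 1, "OPEN": 2}
_INDEX_CLASS = {v: k for k, v in _CLASS_INDEX.items()}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- schemes

def save_scheme(scheme: GatingScheme, path: str | Path) -> None:
    """Write a scheme definition as YAML; round-trips losslessly."""
    Path(path).write_text(yaml.safe_dump(scheme.to_definition(), sort_keys=False))


def load_scheme(path: str | Path) -> GatingScheme:
    return build_scheme(yaml.safe_load(Path(path).read_text()))


# ----------------------------------------------------------- event tables

def write_event_table(
    record: IdealizedRecord, path: str | Path, dialect: str = "dwt"
) -> None:
    """Write an idealized record as a DWT-style or CSV event table."""
    path = Path(path)
    if dialect == "dwt":
        lines = [
            f"Segment: 1  Dwells: {record.n_events}  Start: 0.000000  "
            f"ClassCount: {len(set(record.classes))}  DeadTime(ms): {record.dead_time_ms:.6f}"
        ]
        for c, d in zip(record.classes, record.durations_ms):
            lines.append(f"{_CLASS_INDEX[c]}\t{d:.6f}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "csv":
        import pandas as pd

        df = record_frame(record)
        header = (
            f"# dead_time_ms={record.dead_time_ms:.6f}"
            f" sampling_rate={record.sampling_rate or ''}"
            f" holding_mV={record.holding_potential_mV if record.holding_potential_mV is not None else ''}"
            f" source={record.source}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def record_frame(record: IdealizedRecord):
    """Record as a pandas DataFrame (state, class, duration_ms, amplitude_pA)."""
    import pandas as pd

    states = record.states if record.states is not None else [""] * record.n_events
    return pd.DataFrame(
        {
            "state": list(states),
            "class": list(record.classes),
            "duration_ms": record.durations_ms,
            "amplitude_pA": record.amplitudes_pA,
        }
    )


def read_event_table(path: str | Path, dialect: str | None = None) -> IdealizedRecord:
    """Read a DWT-style or CSV event table (dialect inferred from the
    extension when not given)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "dwt"
    if dialect == "dwt":
        return _read_dwt(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dwt(path: Path) -> IdealizedRecord:
    classes, durations = [], []
    dead_time = 0.0
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("Segment:"):
            if "DeadTime(ms):" in line:
                dead_time = float(line.split("DeadTime(ms):")[1].split()[0])
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected class and duration")
        try:
            ci = int(parts[0])
            dur = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
        if ci not in _INDEX_CLASS:
            raise ParseError(f"{path}:{ln}: unknown class index {ci}")
        if dur <= 0:
            raise ParseError(f"{path}:{ln}: non-positive duration {dur}")
        classes.append(_INDEX_CLASS[ci])
        durations.append(dur)
    if not classes:
        raise ParseError(f"{path}: no events")
    return IdealizedRecord(
        classes=np.array(classes, dtype=object),
        durations_ms=np.array(durations),
        amplitudes_pA=np.zeros(len(durations)),
        dead_time_ms=dead_time,
        source="idealized",
    )


def _read_csv(path: Path) -> IdealizedRecord:
    import pandas as pd

    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if (df["duration_ms"] <= 0).any():
        bad = int(df.index[df["duration_ms"] <= 0][0]) + 2 + (1 if meta else 0)
        raise ParseError(f"{path}:{bad}: non-positive duration")
    states = df["state"].fillna("").astype(str).to_numpy(dtype=object) if "state" in df else None
    if states is not None and not np.any(states != ""):
        states = None
    return IdealizedRecord(
        classes=df["class"].to_numpy(dtype=object),
        durations_ms=df["duration_ms"].to_numpy(dtype=float),
        amplitudes_pA=(
            df["amplitude_pA"].to_numpy(dtype=float)
            if "amplitude_pA" in df
            else np.zeros(len(df))
        ),
        states=states,
        dead_time_ms=float(meta.get("dead_time_ms", 0.0)),
        sampling_rate=float(meta["sampling_rate"]) if meta.get("sampling_rate") else None,
        holding_potential_mV=float(meta["holding_mV"]) if meta.get("holding_mV") else None,
        source=meta.get("source", "idealized"),
    )


# ---------------------------------------------------------------- traces

def write_trace(trace: Trace, path: str | Path, fmt: str = "text") -> None:
    """Write a trace: 'text' (# header lines + one sample per line, pA) or
    'raw' (JSON header at ``path`` plus little-endian float32 samples at
    ``path`` with suffix '.f32')."""
    path = Path(path)
    header = {
        "sampling_rate_Hz": trace.sampling_rate,
        "filter_cutoff_Hz": trace.filter_cutoff,
        "noise_sd_pA": trace.noise_sd,
        "holding_potential_mV": trace.holding_potential_mV,
        "units": "pA",
        "n_samples": trace.n_samples,
    }
    if fmt == "text":
        with open(path, "w") as fh:
            for k, v in header.items():
                fh.write(f"# {k}={v}\n")
            np.savetxt(fh, trace.samples, fmt="%.5f")
    elif fmt == "raw":
        header["samples_file"] = path.with_suffix(path.suffix + ".f32").name
        header["dtype"] = "<f4"
        path.write_text(json.dumps(header, indent=1))
        trace.samples.astype("<f4").tofile(path.with_suffix(path.suffix + ".f32"))
    else:
        raise ValueError(f"unknown trace format {fmt!r}")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        header = json.loads(text)
        samples = np.fromfile(
            path.parent / header["samples_file"], dtype=header.get("dtype", "<f4")
        ).astype(float)
    else:
        header = {}
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                header[k.strip()] = v.strip()
            elif line.strip():
                rows.append(float(line))
        samples = np.array(rows)

    def fnum(key, default=None):
        v = header.get(key)
        if v in (None, "", "None"):
            return default
        return float(v)

    return Trace(
        samples=samples,
        sampling_rate=fnum("sampling_rate_Hz", 20_000.0),
        filter_cutoff=fnum("filter_cutoff_Hz"),
        noise_sd=fnum("noise_sd_pA", 0.0) or 0.0,
        holding_potential_mV=fnum("holding_potential_mV"),
    )
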