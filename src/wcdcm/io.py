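"""Plain-text file formats: BOLD series, input timelines, evidence tables,
model specifications and run configurations.

All files use seconds; series files are row-per-sample with the region
order given by the header, and carry their sampling interval in a leading
comment line (``# TR=2.0`` for BOLD, ``# dt=0.125`` for inputs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import FormatError, InvalidParameterError
from .generative import BOLDSeries, InputTimeline
from .neuronal import ModelSpec

__all__ = [
    "read_bold_tsv", "write_bold_tsv",
    "read_inputs", "write_inputs_tsv",
    "read_evidence_tsv", "write_evidence_tsv",
    "read_spec_json", "write_spec_json",
]


def _header_value(line: str, key: str, path, lineno: int) -> float:
    try:
        k, v = line.lstrip("#").strip().split("=")
    except ValueError:
        raise FormatError(f"{path}:{lineno}: malformed header comment "
                          f"{line.strip()!r}") from None
    if k.strip() != key:
        raise FormatError(f"{path}:{lineno}: expected '# {key}=<value>', "
                          f"got {line.strip()!r}")
    try:
        return float(v)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric {key} "
                          f"value {v!r}") from None


def _read_table(path, key: str):
    """Parse a commented-header TSV; returns (value, names, matrix)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    value = None
    names = None
    rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            value = _header_value(line, key, path, lineno)
            continue
        if names is None:
            names = line.rstrip("\n").split("\t")
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) != len(names):
            raise FormatError(f"{path}:{lineno}: expected {len(names)} "
                              f"columns, found {len(cells)}")
        row = []
        for col, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value "
                                  f"{cell!r} in column {col}") from None
        rows.append(row)
    if value is None:
        raise FormatError(f"{path}: missing '# {key}=' header comment")
    if names is None or not rows:
        raise FormatError(f"{path}: no data rows")
    return value, names, np.asarray(rows)


def read_bold_tsv(path) -> BOLDSeries:
    """Read a BOLD series TSV: ``# TR=<s>`` comment, header of region
    names, one row per TR sample. Fails loudly on ragged or non-numeric
    rows, naming the offending line."""
    tr, names, y = _read_table(path, "TR")
    return BOLDSeries(TR=tr, y=y, region_names=tuple(names))


def write_bold_tsv(path, series: BOLDSeries) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# TR={series.TR!r}\n")
        fh.write("\t".join(series.region_names) + "\n")
        for row in series.y:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_inputs(path, dt: float | None = None,
                duration: float | None = None) -> InputTimeline:
    """Read an input timeline.

    Two formats are accepted: a sampled TSV with a ``# dt=<s>`` header
    (column per input, row per microtime step), or an event-list TSV with
    columns ``name``, ``onset``, ``duration`` (and optional ``amplitude``)
    compiled to the grid — the latter requires ``dt``; ``duration``
    defaults to the last event offset.
    """
    path = Path(path)
    first = ""
    for line in path.read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            first = line
            break
    if first.split("\t")[0] == "name":
        events = []
        lines = path.read_text().splitlines()
        header = None
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if header is None:
                header = cells
                continue
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: event rows need at "
                                  "least name, onset, duration")
            events.append(tuple([cells[0]] + [float(c) for c in cells[1:]]))
        if dt is None:
            raise InvalidParameterError("event-list inputs require dt")
        if duration is None:
            duration = max(e[1] + e[2] for e in events) if events else 0.0
        return InputTimeline.from_events(events, dt=dt, duration=duration)
    dt_file, names, u = _read_table(path, "dt")
    return InputTimeline(dt=dt_file, u=u.T, names=tuple(names))


def write_inputs_tsv(path, timeline: InputTimeline) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dt={timeline.dt!r}\n")
        fh.write("\t".join(timeline.names) + "\n")
        for row in timeline.u.T:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_evidence_tsv(path):
    """Evidence table TSV: header of model labels, one row per subject."""
    from .comparison import EvidenceTable
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()
             and not ln.startswith("#")]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header and at least one subject")
    labels = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(labels):
            raise FormatError(f"{path}:{lineno}: expected {len(labels)} "
                              f"columns, found {len(cells)}")
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric entry") from None
    return EvidenceTable(F=np.asarray(rows), model_labels=tuple(labels))


def write_evidence_tsv(path, table) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(table.model_labels) + "\n")
        for row in table.F:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def write_spec_json(path, spec: ModelSpec) -> None:
    doc = {
        "region_names": list(spec.region_names),
        "A_mask": spec.A_mask.astype(int).tolist(),
        "B_masks": spec.B_masks.astype(int).tolist(),
        "C_mask": spec.C_mask.astype(int).tolist(),
        "variant": spec.variant,
        "states": spec.states,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_spec_json(path) -> ModelSpec:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"{path}: invalid JSON ({err})") from None
    required = {"region_names", "A_mask", "B_masks", "C_mask",
                "variant", "states"}
    unknown = set(doc) - required
    if unknown:
        raise FormatError(f"{path}: unknown keys {sorted(unknown)}")
    missing = required - set(doc)
    if missing:
        raise FormatError(f"{path}: missing keys {sorted(missing)}")
    return ModelSpec(tuple(doc["region_names"]),
                     np.asarray(doc["A_mask"], dtype=bool),
                     np.asarray(doc["B_masks"], dtype=bool),
                     np.asarray(doc["C_mask"], dtype=bool),
                     variant=doc["variant"], states=doc["states"])
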