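"""Reading and writing the package's plain-text formats.

* Fragment TSV: a ``# n=<n> K=<K> colors=<c1,c2,...>`` header comment, then
  one tab-separated row per fragment: ``fragment_id  start  end
  count_<c1> ... count_<cK>`` with an optional trailing ``sequence`` column.
* Reference-rate TSV: ``residue  rate_per_hour`` or ``residue  class`` rows,
  used to benchmark predictions against e.g. NMR-derived rates.
* Solution JSON: optimum, formulation tag and the enumerated part-level
  count solutions with their expansion multiplicities.

Intervals are 1-based inclusive everywhere, as in the fragment tables this
mirrors; nothing in this module converts coordinates.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import TextIO

import numpy as np

from .model import (
    CountSolution,
    Instance,
    Interval,
    Partition,
    ValidationError,
)

__all__ = [
    "load_instance",
    "write_instance",
    "load_reference_table",
    "write_reference_table",
    "solution_set_to_json",
    "write_solution_json",
    "load_solution_json",
]

_META_RE = re.compile(r"#\s*n=(\d+)\s+K=(\d+)\s+colors=([\w,\- ]+)")


def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [tok.strip() for tok in line.split("\t")]
    # tolerate comma- or space-separated tables
    return [tok for tok in re.split(r"[,\s]+", line.strip()) if tok]


def load_instance(
    path: str | Path | TextIO,
    *,
    drop_protein_n_terminus: bool = False,
    drop_first_residue_per_fragment: bool = False,
) -> Instance:
    """Parse a fragment TSV into an :class:`Instance`.

    Preprocessing flags handle amide hydrogens that never report exchange:

    ``drop_protein_n_terminus``
        Remove residue 1 from every fragment containing it (the protein's
        N-terminal amide is not observable).
    ``drop_first_residue_per_fragment``
        Increment every fragment's start by one (the first residue of each
        peptide back-exchanges during analysis); length-1 fragments are
        dropped with a warning.  Requirements are left unchanged unless the
        table carries ``drop_<color>`` decrement columns.

    Both are off by default: inputs are assumed already reduced.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()

    n = K = None
    color_names: tuple[str, ...] | None = None
    rows: list[tuple[int, list[str]]] = []
    drop_columns = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            m = _META_RE.search(line)
            if m and n is None:
                n = int(m.group(1))
                K = int(m.group(2))
                color_names = tuple(c.strip() for c in m.group(3).split(","))
            if "drop_" in line:
                drop_columns = True
            continue
        rows.append((lineno, _split_row(line)))
    if n is None or color_names is None:
        raise ValidationError("missing '# n=<int> K=<int> colors=...' header")
    if len(color_names) != K:
        raise ValidationError("colors= list length does not match K")

    fragments: list[Interval] = []
    requirements: list[list[int]] = []
    decrements: list[list[int]] = []
    labels: str | None = None
    for lineno, toks in rows:
        n_extra = len(toks) - (3 + K)
        if n_extra not in (0, 1) and not (drop_columns and n_extra in (K, K + 1)):
            raise ValidationError(f"row {lineno}: expected 3+{K} columns, got {len(toks)}")
        try:
            start, end = int(toks[1]), int(toks[2])
            counts = [int(t) for t in toks[3 : 3 + K]]
            dec = [int(t) for t in toks[3 + K : 3 + 2 * K]] if drop_columns and n_extra >= K else [0] * K
        except ValueError as exc:
            raise ValidationError(f"row {lineno}: malformed value ({exc})") from None
        if end < start:
            raise ValidationError(f"row {lineno}: end {end} < start {start}")
        if end > n:
            raise ValidationError(f"row {lineno}: end {end} > n={n}")
        if any(c < 0 for c in counts):
            raise ValidationError(f"row {lineno}: negative count")
        fragments.append(Interval(start, end))
        requirements.append(counts)
        decrements.append(dec)

    req = np.array(requirements, dtype=np.int64).reshape(len(fragments), K)
    dec = np.array(decrements, dtype=np.int64).reshape(len(fragments), K)

    if drop_protein_n_terminus:
        new_fragments = []
        keep = []
        for i, f in enumerate(fragments):
            if f.start == 1:
                if f.end == 1:
                    warnings.warn(f"fragment {i + 1} reduced to nothing; dropped")
                    continue
                f = Interval(2, f.end)
            new_fragments.append(f)
            keep.append(i)
        fragments, req, dec = new_fragments, req[keep], dec[keep]
    if drop_first_residue_per_fragment:
        new_fragments = []
        keep = []
        for i, f in enumerate(fragments):
            if len(f) == 1:
                warnings.warn(f"fragment {i + 1} has length 1; dropped")
                continue
            new_fragments.append(Interval(f.start + 1, f.end))
            keep.append(i)
        fragments = new_fragments
        req = np.maximum(req[keep] - dec[keep], 0)

    return Instance(n=n, fragments=fragments, requirements=req, color_names=color_names,
                    residue_labels=labels)


def write_instance(instance: Instance, path: str | Path | TextIO) -> None:
    """Write the canonical fragment TSV (round-trips byte-identically)."""
    lines = [
        f"# n={instance.n} K={instance.K} colors={','.join(instance.color_names)}",
        "# fragment_id\tstart\tend\t" + "\t".join(f"count_{c}" for c in instance.color_names),
    ]
    for i, f in enumerate(instance.fragments, start=1):
        counts = "\t".join(str(int(c)) for c in instance.requirements[i - 1])
        lines.append(f"{i}\t{f.start}\t{f.end}\t{counts}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# reference rates
# ---------------------------------------------------------------------------


def load_reference_table(path: str | Path | TextIO) -> dict[int, float | str]:
    """Read a per-residue reference table.

    Returns a mapping residue -> rate in 1/h (float) or class label (str);
    residues absent from the table count as missing.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    out: dict[int, float | str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = _split_row(line)
        if len(toks) != 2:
            raise ValidationError(f"row {lineno}: expected 2 columns")
        residue = int(toks[0])
        try:
            out[residue] = float(toks[1])
        except ValueError:
            out[residue] = toks[1]
    return out


def write_reference_table(
    reference: dict[int, float | str], path: str | Path | TextIO
) -> None:
    lines = ["# residue\tvalue"]
    for residue in sorted(reference):
        value = reference[residue]
        if isinstance(value, float):
            lines.append(f"{residue}\t{value:g}")
        else:
            lines.append(f"{residue}\t{value}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# solution sets
# ---------------------------------------------------------------------------


def solution_set_to_json(solution_set) -> dict:
    """JSON-serializable view of a part-level :class:`~hdxresolve.ilp.SolutionSet`."""
    solutions = [
        {"y": sol.y.tolist(), "expansions": int(mult)}
        for sol, mult in zip(solution_set.solutions, solution_set.multiplicities)
    ]
    return {
        "optimum": int(solution_set.optimum),
        "formulation": solution_set.formulation,
        "solutions": solutions,
        "n_solutions": len(solutions),
        "n_expanded": int(sum(solution_set.multiplicities)),
    }


def write_solution_json(solution_set, path: str | Path | TextIO) -> None:
    doc = solution_set_to_json(solution_set)
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def load_solution_json(path: str | Path | TextIO):
    from .ilp import SolutionSet

    if hasattr(path, "read"):
        doc = json.load(path)
    else:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    solutions = [CountSolution(np.array(s["y"], dtype=np.int64)) for s in doc["solutions"]]
    multiplicities = [int(s["expansions"]) for s in doc["solutions"]]
    return SolutionSet(
        optimum=int(doc["optimum"]),
        formulation=doc.get("formulation", "improved"),
        solutions=solutions,
        multiplicities=multiplicities,
    )
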