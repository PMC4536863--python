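"""Reading and writing the package's file formats.

Canonical band-matrix dialect
-----------------------------
Tab-separated UTF-8 text.  The header row starts with ``band_id`` followed by
two columns per sample named ``<sample>_H`` and ``<sample>_M`` (HpaII and
MspI lanes of the paired digest).  Cells are ``0``, ``1`` or ``NA``; ``NA``
is a genuinely missing call and is never silently read as absence.

Metadata files are TSV with columns ``sample_id``, ``population``,
``generation``, ``excluded``.

Dendrograms are serialized to Newick with ultrametric branch lengths on the
dissimilarity scale (node depth = merge height / 2, so the path length
between two leaves equals their cophenetic dissimilarity) and per-node
comments carrying the SIMPROF annotation.

Reports are JSON documents with deterministic key order; floats round-trip
at full precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bands import MISSING, BandMatrix, SampleMetadata
from .cluster import Dendrogram
from .errors import BandMatrixFormatError, DegenerateTreeError

_CELL = {"0": 0, "1": 1, "NA": MISSING}
_CELL_INV = {0: "0", 1: "1", MISSING: "NA"}


def read_band_matrix(
    path: str | Path,
    assay: str = "MSAP",
    te_family: str | None = None,
    sep: str = "\t",
) -> BandMatrix:
    """Read a band matrix from the canonical TSV dialect.

    Raises
    ------
    BandMatrixFormatError
        If a sample has only one of its two lane columns, a column name
        does not follow the ``<sample>_H``/``<sample>_M`` convention, or a
        cell is not ``0``, ``1`` or ``NA`` (the error names the offending
        row and column).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if not header or header[0] != "band_id":
            raise BandMatrixFormatError(
                f"{path}: first header column must be 'band_id', got "
                f"{header[0]!r}" if header else f"{path}: empty file"
            )
        lanes: dict[str, set[str]] = {}
        order: list[str] = []
        for col in header[1:]:
            m = re.fullmatch(r"(.+)_([HM])", col)
            if not m:
                raise BandMatrixFormatError(
                    f"{path}: column {col!r} does not match '<sample>_H' or "
                    f"'<sample>_M'"
                )
            sample, lane = m.group(1), m.group(2)
            if sample not in lanes:
                lanes[sample] = set()
                order.append(sample)
            if lane in lanes[sample]:
                raise BandMatrixFormatError(
                    f"{path}: duplicate lane column {col!r}"
                )
            lanes[sample].add(lane)
        for sample, seen in lanes.items():
            if seen != {"H", "M"}:
                missing_lane = ({"H", "M"} - seen).pop()
                raise BandMatrixFormatError(
                    f"{path}: sample {sample!r} is missing its "
                    f"{missing_lane} lane column (paired digest design "
                    f"requires both)"
                )
        col_of = {c: i for i, c in enumerate(header[1:])}
        band_ids: list[str] = []
        rows_h: list[list[int]] = []
        rows_m: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(sep)
            if len(cells) != len(header):
                raise BandMatrixFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got "
                    f"{len(cells)}"
                )
            band_ids.append(cells[0])
            parsed = []
            for j, raw in enumerate(cells[1:]):
                if raw not in _CELL:
                    raise BandMatrixFormatError(
                        f"{path}:{lineno}: non-binary cell {raw!r} in column "
                        f"{header[j + 1]!r}"
                    )
                parsed.append(_CELL[raw])
            rows_h.append([parsed[col_of[f"{s}_H"]] for s in order])
            rows_m.append([parsed[col_of[f"{s}_M"]] for s in order])
    return BandMatrix(
        band_ids=band_ids,
        sample_ids=order,
        h=np.array(rows_h, dtype=np.int8).reshape(len(band_ids), len(order)),
        m=np.array(rows_m, dtype=np.int8).reshape(len(band_ids), len(order)),
        assay=assay,
        te_family=te_family,
    )


def write_band_matrix(bands: BandMatrix, path: str | Path) -> None:
    """Write a band matrix in the canonical dialect (bit-stable round trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        cols = ["band_id"]
        for s in bands.sample_ids:
            cols += [f"{s}_H", f"{s}_M"]
        fh.write("\t".join(cols) + "\n")
        for i, band in enumerate(bands.band_ids):
            cells = [band]
            for j in range(bands.n_samples):
                cells.append(_CELL_INV[int(bands.h[i, j])])
                cells.append(_CELL_INV[int(bands.m[i, j])])
            fh.write("\t".join(cells) + "\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise BandMatrixFormatError(f"{path}: missing 'sample_id' column")
    table = table.set_index("sample_id")
    return SampleMetadata(table)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out["excluded"] = out["excluded"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", lineterminator="\n")


def _newick_comment(dend: Dendrogram, node: int) -> str:
    ann = dend.simprof.get(node)
    if ann is None:
        return ""
    if not ann.testable:
        return "[&simprof=untestable]"
    if not ann.tested:
        return "[&simprof=homogeneous]"  # inherited via the stopping rule
    flag = "significant" if ann.significant else "homogeneous"
    return f"[&simprof={flag},pi={ann.pi:.6g},p={ann.p:.6g}]"


def newick_string(dend: Dendrogram) -> str:
    """Render a dendrogram as Newick.

    Node depth is merge height / 2 so the tree is ultrametric and the
    leaf-to-leaf path length equals the pair's cophenetic dissimilarity
    (1 - similarity).  Internal-node comments carry the SIMPROF verdict.
    """
    n = len(dend.leaf_ids)
    if n < 2:
        raise DegenerateTreeError("cannot serialize a tree with <2 leaves")
    heights = {i: 0.0 for i in range(n)}
    for k, (left, right, h) in enumerate(dend.merges):
        heights[n + k] = h / 2.0

    def render(node: int, parent_depth: float) -> str:
        depth = heights[node]
        blen = parent_depth - depth
        if node < n:
            return f"{dend.leaf_ids[node]}:{blen:.6g}"
        left, right, _ = dend.merges[node - n]
        inner = f"({render(left, depth)},{render(right, depth)})"
        return f"{inner}{_newick_comment(dend, node)}:{blen:.6g}"

    root = n + len(dend.merges) - 1
    left, right, _ = dend.merges[-1]
    depth = heights[root]
    body = f"({render(left, depth)},{render(right, depth)})"
    return f"{body}{_newick_comment(dend, root)};"


def write_newick(dend: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(dend) + "\n", encoding="utf-8")


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write a pipeline report as JSON (insertion key order, full precision)."""
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=2, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
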