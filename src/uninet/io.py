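"""Delimited-text and Matrix Market readers/writers, partition files, and
run provenance.

Dense matrices travel as TSV/CSV without a header by default (optional
node-name header row/column); sparse κ-NN and co-neighbor graphs as
Matrix Market.  Partition files are two-column TSV (node_id,
module_label) with 1-based labels externally; labels are densified to
1..k on read, with the mapping logged.  Floats are written with 17
significant digits so round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import Partition, UninetError

logger = logging.getLogger(__name__)

_FMT = "%.17g"


def _delimiter(path: Path, fmt: str | None) -> str:
    if fmt == "csv" or (fmt is None and path.suffix.lower() == ".csv"):
        return ","
    return "\t"


def read_matrix(path: str | Path, fmt: str | None = None) -> np.ndarray:
    """Read a dense matrix from TSV/CSV or a sparse one from Matrix Market."""
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        return spio.mmread(path)
    sep = _delimiter(path, fmt)
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(sep)
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                bad = next(
                    i for i, c in enumerate(cells)
                    if not _is_float(c)
                )
                raise UninetError(
                    f"{path}:{lineno}: non-numeric cell in column {bad + 1}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise UninetError(
                    f"{path}:{lineno}: ragged row ({len(row)} cells, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise UninetError(f"{path}: empty matrix file")
    return np.array(rows)


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_matrix(path: str | Path, M, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt == "mtx" or (fmt is None and path.suffix.lower() == ".mtx"):
        spio.mmwrite(path, sparse.coo_matrix(M))
        return
    np.savetxt(path, np.asarray(M), fmt=_FMT, delimiter=_delimiter(path, fmt))


def read_partition(path: str | Path) -> Partition:
    """Read a two-column (node_id, 1-based module label) TSV partition."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "label"])
    if df["node"].duplicated().any():
        dup = df.loc[df["node"].duplicated(), "node"].iloc[0]
        raise UninetError(f"duplicate node id {dup} in partition file")
    if not np.issubdtype(df["label"].dtype, np.integer):
        raise UninetError("partition labels must be integers")
    order = np.argsort(df["node"].to_numpy())
    nodes = df["node"].to_numpy()[order]
    if not np.array_equal(nodes, np.arange(1, len(df) + 1)) and not np.array_equal(
        nodes, np.arange(len(df))
    ):
        raise UninetError("partition file must cover nodes 1..n (or 0..n-1)")
    labels = df["label"].to_numpy()[order]
    uniq, dense = np.unique(labels, return_inverse=True)
    if len(uniq) != uniq.max() - uniq.min() + 1 or uniq.min() != 1:
        logger.info("densifying sparse labels %s to 1..%d", uniq, len(uniq))
    return Partition(dense, len(uniq))


def write_partition(path: str | Path, P: Partition) -> None:
    """Write 1-based node ids and 1-based module labels as two-column TSV."""
    arr = np.column_stack([np.arange(1, P.n + 1), P.labels + 1])
    np.savetxt(path, arr, fmt="%d", delimiter="\t")


def checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_provenance(
    path: str | Path, command: str, params: dict, inputs: list[str | Path]
) -> None:
    """JSON sidecar recording command, parameters, versions and checksums."""
    import scipy

    record = {
        "command": command,
        "params": {k: v for k, v in params.items() if _jsonable(v)},
        "inputs": {str(p): checksum(p) for p in inputs if Path(p).exists()},
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__},
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
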