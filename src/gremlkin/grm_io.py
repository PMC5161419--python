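"""GRM binary triad serialization.

The de-facto interchange format used by GREML tooling: three files per
prefix —

* ``<prefix>.grm.bin`` — little-endian float32 lower triangle including
  the diagonal, streamed row-major (pair (i,k) with k <= i at offset
  i(i+1)/2 + k);
* ``<prefix>.grm.N.bin`` — float32 per-pair non-missing SNP counts in
  the same order;
* ``<prefix>.grm.id`` — tab-separated FID IID, one row per sample.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .matrices import RelationshipMatrix

__all__ = ["write_grm_binary", "read_grm_binary"]


def _tri_indices(n: int):
    return np.tril_indices(n)


def write_grm_binary(matrix: RelationshipMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows, cols = _tri_indices(matrix.n)
    matrix.values[rows, cols].astype("<f4").tofile(prefix.parent / (prefix.name + ".grm.bin"))
    counts = matrix.pair_counts
    if counts is None:
        counts = np.ones_like(matrix.values)
    counts[rows, cols].astype("<f4").tofile(
        prefix.parent / (prefix.name + ".grm.N.bin")
    )
    with open(prefix.parent / (prefix.name + ".grm.id"), "w") as fh:
        for sid in matrix.sample_ids:
            fid, _, iid = sid.partition(":")
            if not iid:
                fid, iid = sid, sid
            fh.write(f"{fid}\t{iid}\n")


def read_grm_binary(prefix, kind: str = "other") -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = []
    for line in open(prefix.parent / (prefix.name + ".grm.id")):
        tok = line.split()
        if tok:
            ids.append(tok[1] if tok[0] == tok[1] else f"{tok[0]}:{tok[1]}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate FID-IID pair in .grm.id")
    n = len(ids)
    n_rec = n * (n + 1) // 2
    tri = np.fromfile(prefix.parent / (prefix.name + ".grm.bin"), dtype="<f4")
    if tri.size != n_rec:
        raise ValueError(
            f"{prefix}.grm.bin holds {tri.size} records but {n} ids imply "
            f"n(n+1)/2 = {n_rec}"
        )
    values = np.zeros((n, n))
    rows, cols = _tri_indices(n)
    values[rows, cols] = tri
    values[cols, rows] = tri
    pair_counts = None
    n_path = prefix.parent / (prefix.name + ".grm.N.bin")
    if n_path.exists():
        cnt = np.fromfile(n_path, dtype="<f4")
        if cnt.size != n_rec:
            raise ValueError(
                f"{n_path} holds {cnt.size} records, expected {n_rec}"
            )
        pair_counts = np.zeros((n, n))
        pair_counts[rows, cols] = cnt
        pair_counts[cols, rows] = cnt
    return RelationshipMatrix(ids, values, kind=kind, pair_counts=pair_counts)
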