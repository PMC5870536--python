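"""Align-to-existing-alignment backends.

`mafft --add` is the reference adapter.  The builtin fallback performs a
global profile-to-sequence alignment with affine gaps (BLOSUM62, gap open 11,
gap extend 1): profile columns are scored as the mean BLOSUM62 similarity of
the query residue to the column's residues, weighted by column occupancy, so
gappy columns attract gaps naturally.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .alignment_areas import (
    AA20,
    GAP,
    Alignment,
    MissingExternalToolError,
    ProteinSequence,
    normalize_residues,
)

logger = logging.getLogger(__name__)

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
_NEG = -1e30


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for a in AA20:
        for b in AA20:
            out[_AA_INDEX[a], _AA_INDEX[b]] = mat[a][b]
    return out


_B62 = _blosum62()


def _unique_query_id(alignment: Alignment, query_id: str) -> str:
    qid = query_id
    while qid in alignment.ids:
        qid += "_query"
    if qid != query_id:
        logger.warning("query id %r clashes with an alignment row; using %r",
                       query_id, qid)
    return qid


def mafft_add(alignment: Alignment, query: ProteinSequence) -> Alignment:
    import shutil

    if shutil.which("mafft") is None:
        raise MissingExternalToolError(
            "mafft not found on PATH; install MAFFT or use method='builtin'"
        )
    qid = _unique_query_id(alignment, query.id)
    with tempfile.TemporaryDirectory() as tmp:
        existing = Path(tmp) / "existing.fa"
        new = Path(tmp) / "query.fa"
        alignment.to_fasta(existing)
        new.write_text(f">{qid}\n{query.residues}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", "--add", str(new), str(existing)],
            capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"mafft --add failed: {proc.stderr.strip()}")
        ids, rows = [], []
        from io import StringIO

        for rec in SeqIO.parse(StringIO(proc.stdout), "fasta"):
            ids.append(rec.id)
            rows.append(normalize_residues(str(rec.seq), allow_gap=True, seq_id=rec.id))
    if tuple(ids[:-1]) != alignment.ids or ids[-1] != qid:
        raise RuntimeError("mafft --add changed row order unexpectedly")
    return Alignment(ids=tuple(ids), rows=tuple(rows),
                     family_label=alignment.family_label)


def _column_profile(alignment: Alignment) -> np.ndarray:
    """(n_cols, 20) occupancy-weighted residue frequencies."""
    prof = np.zeros((alignment.n_cols, 20))
    for row in alignment.rows:
        for j, ch in enumerate(row):
            k = _AA_INDEX.get(ch)
            if k is not None:
                prof[j, k] += 1.0
    return prof / alignment.n_rows


def builtin_add(alignment: Alignment, query: ProteinSequence) -> Alignment:
    """Global affine-gap Needleman-Wunsch of the query against the profile."""
    qid = _unique_query_id(alignment, query.id)
    q = query.residues
    m, n = len(q), alignment.n_cols
    prof = _column_profile(alignment)  # (n, 20)
    # S[i, j]: score of matching query residue i to column j; 'X' scores 0.
    emis = np.zeros((m, 20))
    for i, ch in enumerate(q):
        k = _AA_INDEX.get(ch)
        if k is not None:
            emis[i] = _B62[k]
    S = emis @ prof.T  # (m, n)

    # Three-state affine DP.  M: i<->j match; Ix: query residue vs gap column
    # (insertion into the alignment); Iy: gap in query vs column j.
    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)
    Iy = np.full((m + 1, n + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, n + 1):
        Iy[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    ext = GAP_EXTEND * np.arange(n + 1)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        Ix[i] = np.maximum(M[i - 1] - GAP_OPEN, Ix[i - 1] - GAP_EXTEND)
        # Iy[i, j] = max_{k<j} (M[i, k] + ext[k]) - GAP_OPEN - ext[j - 1]
        run = np.maximum.accumulate(M[i] + ext)
        Iy[i, 1:] = run[:-1] - GAP_OPEN - ext[:-1]

    # Traceback by re-deriving transitions from the stored matrices.
    i, j = m, n
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    ops: list[str] = []  # 'M' consume (qi, colj); 'I' consume qi; 'D' consume colj
    while i > 0 or j > 0:
        if state == 0:  # M
            ops.append("M")
            prev = [M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
            if i == 0 and j == 0:
                break
        elif state == 1:  # Ix: query insertion
            ops.append("I")
            state = 0 if np.isclose(Ix[i, j], M[i - 1, j] - GAP_OPEN) else 1
            i -= 1
        else:  # Iy: gap in query
            ops.append("D")
            state = 0 if np.isclose(Iy[i, j], M[i, j - 1] - GAP_OPEN) else 2
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0 and state != 2:
            state = 2
        if j == 0 and state != 1:
            state = 1
    ops.reverse()

    qrow: list[str] = []
    new_rows = [list() for _ in alignment.rows]  # type: list[list[str]]
    qi = 0
    cj = 0
    for op in ops:
        if op == "M":
            qrow.append(q[qi])
            for r, row in zip(new_rows, alignment.rows):
                r.append(row[cj])
            qi += 1
            cj += 1
        elif op == "I":
            qrow.append(q[qi])
            for r in new_rows:
                r.append(GAP)
            qi += 1
        else:
            qrow.append(GAP)
            for r, row in zip(new_rows, alignment.rows):
                r.append(row[cj])
            cj += 1
    if qi != m or cj != n:
        raise RuntimeError("builtin aligner traceback did not consume all input")
    return Alignment(
        ids=alignment.ids + (qid,),
        rows=tuple("".join(r) for r in new_rows) + ("".join(qrow),),
        family_label=alignment.family_label,
    )
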