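"""Star multiple alignment: project sequences onto a center sequence.

Each sequence is globally aligned to the center; insertion columns
relative to the center are merged by position (one block per center
position, wide enough for the longest insertion any row needs).  The
result is a rectangular matrix of aligned rows — sufficient for
column voting (consensus) and for gap-free column masking (identity
matrices, trees), which is all the pipeline derives from an MSA.
"""

from __future__ import annotations

import numpy as np

from ._align import global_path


def align_to_center(seq: str, center: str) -> tuple[list[str], dict[int, str]]:
    """Align one sequence to the center.

    Returns (per-center-position symbols, insertions), where the symbol
    list has one entry per center position ('A'..'T' or '-') and
    insertions maps center position p to the string inserted before p.
    """
    path = global_path(seq, center)
    cols: list[str] = []
    ins: dict[int, str] = {}
    qi = 0
    for n, op in path:
        if op in ("=", "X", "M"):
            cols.extend(seq[qi:qi + n])
            qi += n
        elif op == "D":  # center consumes, read gapped
            cols.extend("-" * n)
        else:  # 'I': inserted in read relative to center, placed before len(cols)
            p = len(cols)
            ins[p] = ins.get(p, "") + seq[qi:qi + n]
            qi += n
    return cols, ins


def star_align(center: str, sequences: list[str]) -> list[str]:
    """Star MSA of ``sequences`` (center included as the first row)."""
    L = len(center)
    aligned = [align_to_center(s, center) for s in sequences]
    ins_width = np.zeros(L + 1, dtype=int)
    for _, ins in aligned:
        for p, s in ins.items():
            ins_width[p] = max(ins_width[p], len(s))

    def build_row(cols: list[str], ins: dict[int, str]) -> str:
        out = []
        for p in range(L + 1):
            if ins_width[p]:
                s = ins.get(p, "")
                out.append(s.ljust(ins_width[p], "-"))
            if p < L:
                out.append(cols[p])
        return "".join(out)

    center_cols, center_ins = list(center), {}
    rows = [build_row(center_cols, center_ins)]
    for cols, ins in aligned:
        rows.append(build_row(cols, ins))
    return rows
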