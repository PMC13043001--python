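"""Minimal STAR (RELION dialect) loop reader/writer.

One ``data_`` block with a single ``loop_`` of whitespace-separated
columns — the dialect every picker emits and RELION/CryoSPARC ingest.
Unknown columns are carried through untouched.
"""

from __future__ import annotations


class StarError(ValueError):
    pass


def read_star_loop(path):
    """Parse the first loop in the file.

    Returns (columns, rows) where columns is a list of tag names
    (``_rln...``) and rows a list of token lists (strings).
    """
    columns, rows = [], []
    in_loop = False
    header_done = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                if header_done and rows:
                    break  # blank line terminates the data rows
                continue
            if line.startswith("data_"):
                if header_done and rows:
                    break
                continue
            if line == "loop_":
                if header_done and rows:
                    break
                in_loop, header_done = True, False
                columns = []
                continue
            if in_loop and line.startswith("_"):
                if header_done:
                    break  # a new tag after data rows: next block
                columns.append(line.split()[0])
                continue
            if in_loop and columns:
                header_done = True
                tokens = line.split()
                if len(tokens) != len(columns):
                    raise StarError(
                        f"{path}: row has {len(tokens)} fields, expected "
                        f"{len(columns)}"
                    )
                rows.append(tokens)
    if not columns:
        raise StarError(f"{path}: no loop_ block found")
    return columns, rows


def write_star_loop(path, columns, rows, block="particles"):
    with open(path, "w") as fh:
        fh.write(f"\ndata_{block}\n\nloop_\n")
        for i, col in enumerate(columns, start=1):
            fh.write(f"{col} #{i}\n")
        for row in rows:
            fh.write(" ".join(str(v) for v in row) + "\n")
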