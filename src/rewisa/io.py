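"""Delimited-text I/O for matrices, profiles and reported blocks.

Matrix files are plain TSV (comma selectable): a header row of condition
identifiers and a first column of site identifiers.  Local functional blocks
(LFBs) are written both as a JSON record per block and as a flat TSV
membership table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import MethylationProfile, ProfileError

__all__ = [
    "ParseError",
    "read_matrix",
    "write_matrix",
    "read_profile",
    "write_profile",
    "write_lfbs",
    "read_lfbs",
]


class ParseError(ValueError):
    """Malformed delimited-text input."""


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a labelled site-by-condition matrix from delimited text.

    Raises :class:`ParseError` naming the offending line for ragged rows,
    non-numeric cells and duplicate identifiers (line 1 is the header).
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    rows = [line.split(sep) for line in raw if line != ""]
    if not rows:
        raise ParseError(f"{path}: empty file")
    width = len(rows[0])
    for lineno, fields in enumerate(rows[1:], start=2):
        if len(fields) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {width}"
            )
    header = [c.strip() for c in rows[0][1:]]
    site_ids = [r[0].strip() for r in rows[1:]]
    if len(set(header)) != len(header):
        raise ParseError(f"{path}: line 1: duplicate condition identifiers")
    seen: dict[str, int] = {}
    for lineno, sid in enumerate(site_ids, start=2):
        if sid in seen:
            raise ParseError(
                f"{path}: line {lineno}: duplicate site identifier {sid!r} "
                f"(first seen on line {seen[sid]})"
            )
        seen[sid] = lineno
    values = np.empty((len(site_ids), len(header)), dtype=float)
    for i, fields in enumerate(rows[1:]):
        for j, cell in enumerate(fields[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 2}, column {j + 2}: non-numeric cell {cell!r}"
                ) from None
    return pd.DataFrame(values, index=site_ids, columns=header)


def write_matrix(df_or_values, path, sep: str = "\t", *, site_ids=None, condition_ids=None):
    """Write a labelled matrix as delimited text (header + id column)."""
    if isinstance(df_or_values, pd.DataFrame):
        df = df_or_values
    else:
        df = pd.DataFrame(np.asarray(df_or_values), index=site_ids, columns=condition_ids)
    df.to_csv(path, sep=sep, index_label="site")


def read_profile(path_P, path_W=None, sep: str = "\t", alpha: float = 1e-6) -> MethylationProfile:
    """Read a methylation-level matrix P and its weight matrix W.

    A missing weight file is an explicit error: the weighted algorithm cannot
    run without W, and silently substituting all-ones would change results.
    """
    if path_W is None:
        raise ParseError(
            "no weight-matrix path given; the expression-weighted algorithm needs W "
            "(pass a weight file, or build one with quantify/compute_weights)"
        )
    dfP = read_matrix(path_P, sep=sep)
    dfW = read_matrix(path_W, sep=sep)
    if list(dfP.index) != list(dfW.index) or list(dfP.columns) != list(dfW.columns):
        raise ProfileError(f"{path_P} and {path_W} have different axis labels")
    return MethylationProfile(
        tuple(dfP.index), tuple(dfP.columns), dfP.to_numpy(), dfW.to_numpy(), alpha=alpha
    )


def write_profile(profile: MethylationProfile, path_P, path_W, sep: str = "\t"):
    write_matrix(profile.P, path_P, sep=sep, site_ids=profile.site_ids,
                 condition_ids=profile.condition_ids)
    write_matrix(profile.W, path_W, sep=sep, site_ids=profile.site_ids,
                 condition_ids=profile.condition_ids)


def _lfb_record(i, lfb, site_ids=None, condition_ids=None) -> dict:
    sites = list(lfb.sites)
    conds = list(lfb.conditions)
    rec = {
        "id": f"LFB{i + 1}",
        "sites": [site_ids[u] for u in sites] if site_ids is not None else sites,
        "conditions": [condition_ids[v] for v in conds] if condition_ids is not None else conds,
        "T_R": lfb.t_r,
        "T_C": lfb.t_c,
        "n_iterations": lfb.n_iterations,
    }
    return rec


def write_lfbs(lfbs: Sequence, path_json, path_tsv=None, *, site_ids=None, condition_ids=None):
    """Write blocks as JSON records plus an optional flat membership TSV.

    The JSON file holds one record per block with its site and condition
    identifier lists and the thresholds it was found at.  The TSV lists one
    (block, axis, identifier) membership per line.
    """
    records = [_lfb_record(i, b, site_ids, condition_ids) for i, b in enumerate(lfbs)]
    Path(path_json).write_text(json.dumps(records, indent=1) + "\n")
    if path_tsv is not None:
        lines = ["lfb\taxis\tid"]
        for rec in records:
            lines += [f"{rec['id']}\tsite\t{s}" for s in rec["sites"]]
            lines += [f"{rec['id']}\tcondition\t{c}" for c in rec["conditions"]]
        Path(path_tsv).write_text("\n".join(lines) + "\n")


def read_block_memberships(path_json):
    """Read blocks as raw (sites, conditions) label tuples, no index mapping.

    Suitable for label-based comparison of two block files (e.g. obtained vs
    truth) without knowing the originating matrix.
    """
    records = json.loads(Path(path_json).read_text())
    return [(tuple(str(s) for s in rec["sites"]),
             tuple(str(c) for c in rec["conditions"])) for rec in records]


def read_lfbs(path_json, *, site_ids=None, condition_ids=None):
    """Read blocks back from JSON, mapping identifiers to indices if given."""
    from .isa import LFB  # local import to avoid a cycle

    records = json.loads(Path(path_json).read_text())
    blocks = []
    for rec in records:
        sites = rec["sites"]
        conds = rec["conditions"]
        if site_ids is not None:
            lookup = {s: i for i, s in enumerate(site_ids)}
            sites = [lookup[str(s)] for s in sites]
        if condition_ids is not None:
            lookup = {c: j for j, c in enumerate(condition_ids)}
            conds = [lookup[str(c)] for c in conds]
        blocks.append(
            LFB(
                sites=tuple(int(u) for u in sites),
                conditions=tuple(int(v) for v in conds),
                t_r=float(rec.get("T_R", np.nan)),
                t_c=float(rec.get("T_C", np.nan)),
                n_iterations=int(rec.get("n_iterations", 0)),
                converged=True,
            )
        )
    return blocks
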