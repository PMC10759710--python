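"""Readers and writers for the package's plain-text interchange formats.

* Count table: TSV with a header row ``site<TAB>transitions``, one row per
  site, 1-based inclusive coordinates (rCRS convention), preceded by a
  ``#`` comment stating the coordinate convention.
* Transversion-site list: one 1-based integer per line; ``#`` comments and
  blank lines allowed.
* Sequences: FASTA via Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

COUNT_TABLE_COMMENT = "# per-site transition counts; coordinates are 1-based inclusive (rCRS-style)"


def write_count_table(path, counts) -> None:
    """Write per-site transition counts for sites 1..n."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(COUNT_TABLE_COMMENT + "\n")
        fh.write("site\ttransitions\n")
        for i, c in enumerate(counts, start=1):
            fh.write(f"{i}\t{int(c)}\n")


def read_count_table(path) -> np.ndarray:
    """Read a count table back into a dense vector indexed by site - 1.

    Every site from 1 to the maximum present must appear exactly once;
    malformed or duplicate rows raise :class:`ParseError` with the
    offending line number.
    """
    entries: dict[int, int] = {}
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols[:2] != ["site", "transitions"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header 'site\\ttransitions', got {line!r}"
                    )
                header_seen = True
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                site, cnt = int(cols[0]), int(cols[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if site < 1:
                raise ParseError(f"{path}:{lineno}: site index {site} is not 1-based")
            if cnt < 0:
                raise ParseError(f"{path}:{lineno}: negative count {cnt}")
            if site in entries:
                raise ParseError(f"{path}:{lineno}: duplicate site {site}")
            entries[site] = cnt
    if not entries:
        raise ParseError(f"{path}: no count rows found")
    n = max(entries)
    missing = set(range(1, n + 1)) - set(entries)
    if missing:
        raise ParseError(f"{path}: missing sites, e.g. {sorted(missing)[:5]}")
    out = np.zeros(n, dtype=np.int64)
    for site, cnt in entries.items():
        out[site - 1] = cnt
    return out


def write_transversion_sites(path, sites: Iterable[int]) -> None:
    with open(path, "w") as fh:
        fh.write("# 1-based indices of sites with at least one transversion in the phylogeny\n")
        for s in sorted(int(s) for s in sites):
            fh.write(f"{s}\n")


def read_transversion_sites(path) -> set[int]:
    sites: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                site = int(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer site index {line!r}") from exc
            if site < 1:
                raise ParseError(f"{path}:{lineno}: site index {site} is not 1-based")
            sites.add(site)
    return sites


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a FASTA file as (id, uppercase sequence) pairs."""
    if not os.path.exists(path):
        raise ParseError(f"FASTA file not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_fasta_first(path) -> tuple[str, str]:
    return read_fasta(path)[0]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        path,
        "fasta",
    )
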