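"""Readers and writers for the plain-text interchange formats.

Two formats travel through the package: 2+-column TSV edge lists (``#``
comment lines allowed) handled in :mod:`herbwalk.network`, and GMT gene-set
libraries (one set per line: name, description, then member genes, all
tab-separated) handled here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

from .exceptions import EmptyInputError, ParseError

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT library into ``{set name: member genes}``.

    Duplicate members within a line are collapsed; the description column is
    ignored. Raises :class:`ParseError` on lines with fewer than three
    columns and :class:`EmptyInputError` if no sets are found.
    """
    sets: dict[str, set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(parts)} columns)"
                )
            name = parts[0].strip()
            members = {p.strip() for p in parts[2:] if p.strip()}
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                logger.warning("duplicate gene set %r in %s; keeping first", name, path)
                continue
            sets[name] = members
    if not sets:
        raise EmptyInputError(f"{path}: no gene sets found")
    logger.info("read %d gene sets from %s", len(sets), path)
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path,
              description: str = "herbwalk") -> None:
    """Write gene sets as GMT, members sorted for reproducible output."""
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list (``#`` comments allowed)."""
    genes: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    if not genes:
        raise EmptyInputError(f"{path}: no genes found")
    return genes
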