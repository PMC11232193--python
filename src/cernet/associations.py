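"""Association lists and candidate triplet assembly.

A ceRNA triplet (lncRNA x, miRNA z, mRNA y) is a candidate competing-endogenous-RNA
unit: x and y are coupled through their shared sponge interaction with z.  Candidate
triplets are assembled by joining a lncRNA-miRNA association list with an mRNA-miRNA
association list on the shared miRNA, restricted to the RNAs actually measured in the
cohort under analysis.  Association lists typically come from intersecting several
target-prediction / CLIP databases (e.g. miRcode with starBase for lncRNA-miRNA;
miRDB, miRTarBase and TargetScan for mRNA-miRNA), exported as two-column TSV files.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import EmptyInputError, KindMismatchError, ParseError

LNC_MI = "lncRNA-miRNA"
MRNA_MI = "mRNA-miRNA"
_KINDS = (LNC_MI, MRNA_MI)

# "hsa-miR-424-5p" / "hsa-mir-424-5p" style tokens; only the mir token is case-folded
_MIR_TOKEN = re.compile(r"\b(mir|miR|MIR|MiR)\b")
_ARM_SUFFIX = re.compile(r"-(5p|3p)$", re.IGNORECASE)


def normalize_id(identifier: str, *, collapse_arms: bool = False) -> str:
    """Normalize a gene/miRNA identifier to the package's canonical form.

    Identifiers are opaque case-sensitive strings apart from one pass:
    surrounding whitespace is trimmed and the "miR"/"MIR" token of miRNA-style
    names is lowercased, so "hsa-miR-424" and "hsa-mir-424" unify.  With
    ``collapse_arms=True`` a trailing -5p/-3p mature-arm suffix is stripped as
    well (off by default: arm collapsing changes triplet counts).
    """
    out = _MIR_TOKEN.sub("mir", identifier.strip())
    if collapse_arms:
        out = _ARM_SUFFIX.sub("", out)
    return out


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated set of (regulator, miRNA) pairs of one kind."""

    pairs: frozenset[tuple[str, str]]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise KindMismatchError(f"unknown association kind {self.kind!r}; expected one of {_KINDS}")
        for reg, mi in self.pairs:
            if not reg or not mi:
                raise ParseError(f"empty identifier in pair ({reg!r}, {mi!r})")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def regulators(self) -> frozenset[str]:
        return frozenset(reg for reg, _ in self.pairs)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(mi for _, mi in self.pairs)


class Triplet(NamedTuple):
    """One (lncRNA, miRNA, mRNA) candidate unit — the atom of the pipeline."""

    lncrna: str
    mirna: str
    mrna: str

    def label(self) -> str:
        return f"{self.lncrna}_{self.mirna}_{self.mrna}"


def read_association_file(
    path: str | Path,
    kind: str,
    *,
    collapse_arms: bool = False,
    id_mapping: dict[str, str] | None = None,
) -> AssociationTable:
    """Read a two-column TSV of (regulator, miRNA) pairs into an AssociationTable.

    An optional header line is tolerated (detected as a first line whose second
    field does not look like a miRNA and that never recurs as data — in practice:
    skipped when both fields match common header words).  Duplicate rows collapse;
    row order and multiplicity carry no weight.

    Parameters
    ----------
    id_mapping
        Optional regulator-id translation (e.g. Ensembl id -> gene symbol)
        applied after normalization; unmapped ids pass through unchanged.
    """
    if kind not in _KINDS:
        raise KindMismatchError(f"unknown association kind {kind!r}")
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns, found {len(fields)}")
            reg, mi = (normalize_id(f, collapse_arms=collapse_arms) for f in fields)
            if lineno == 1 and _looks_like_header(reg, mi):
                continue
            if not reg or not mi:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            if id_mapping is not None:
                reg = id_mapping.get(reg, reg)
            pairs.add((reg, mi))
    if not pairs:
        raise EmptyInputError(f"{path}: no association records found")
    return AssociationTable(pairs=frozenset(pairs), kind=kind)


_HEADER_WORDS = {
    "lncrna", "lnc", "mirna", "mir", "mirna_id", "mrna", "gene", "gene_id",
    "regulator", "symbol", "target", "id",
}


def _looks_like_header(first: str, second: str) -> bool:
    return first.lower() in _HEADER_WORDS and second.lower() in _HEADER_WORDS


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping file (e.g. ensembl_id<TAB>symbol)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns, found {len(fields)}")
            mapping[fields[0].strip()] = fields[1].strip()
    if not mapping:
        raise EmptyInputError(f"{path}: empty mapping file")
    return mapping


def intersect_associations(tables: Iterable[AssociationTable]) -> AssociationTable:
    """Set-intersect association tables of the same kind.

    This implements the cross-database consensus step: keeping only pairs
    supported by every source list.  Commutative and idempotent.
    """
    tables = list(tables)
    if not tables:
        raise EmptyInputError("intersect_associations: no tables given")
    kinds = {t.kind for t in tables}
    if len(kinds) > 1:
        raise KindMismatchError(f"cannot intersect association tables of mixed kinds {sorted(kinds)}")
    pairs = frozenset.intersection(*(t.pairs for t in tables))
    if not pairs:
        warnings.warn("association intersection is empty", stacklevel=2)
    return AssociationTable(pairs=pairs, kind=tables[0].kind)


def build_initial_triplets(
    lnc_mi: AssociationTable,
    mrna_mi: AssociationTable,
    expressed_lnc: Iterable[str],
    expressed_mi: Iterable[str],
    expressed_mrna: Iterable[str],
) -> set[Triplet]:
    """Join the two association lists on the shared miRNA into candidate triplets.

    Returns ``{(x, z, y) : (x,z) in lnc_mi, (y,z) in mrna_mi}`` restricted to the
    expressed-id sets of the cohort (which is why the initial triplet count is
    cohort-specific).  The count equals the sum over shared miRNAs of
    (#expressed lncRNA partners x #expressed mRNA partners), minus any degenerate
    combinations where two of the three identifiers coincide as strings.
    """
    if lnc_mi.kind != LNC_MI:
        raise KindMismatchError(f"first table must be {LNC_MI}, got {lnc_mi.kind}")
    if mrna_mi.kind != MRNA_MI:
        raise KindMismatchError(f"second table must be {MRNA_MI}, got {mrna_mi.kind}")
    expressed_lnc = set(expressed_lnc)
    expressed_mi = set(expressed_mi)
    expressed_mrna = set(expressed_mrna)
    for name, ids in (("lncRNA", expressed_lnc), ("miRNA", expressed_mi), ("mRNA", expressed_mrna)):
        if not ids:
            warnings.warn(f"expressed {name} id set is empty; triplet set may be empty", stacklevel=2)

    lnc_by_mi: dict[str, list[str]] = {}
    for lnc, mi in lnc_mi.pairs:
        if lnc in expressed_lnc and mi in expressed_mi:
            lnc_by_mi.setdefault(mi, []).append(lnc)
    triplets: set[Triplet] = set()
    for mrna, mi in mrna_mi.pairs:
        if mrna not in expressed_mrna:
            continue
        for lnc in lnc_by_mi.get(mi, ()):
            if lnc != mrna and lnc != mi and mrna != mi:
                triplets.add(Triplet(lnc, mi, mrna))
    return triplets


def write_triplets(path: str | Path, triplets: Iterable[Triplet]) -> None:
    """Write triplets as a 3-column TSV (lncRNA, miRNA, mRNA) with header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("lncRNA\tmiRNA\tmRNA\n")
        for t in sorted(triplets):
            fh.write(f"{t.lncrna}\t{t.mirna}\t{t.mrna}\n")


def read_triplets(path: str | Path) -> set[Triplet]:
    """Read a triplet TSV written by :func:`write_triplets`."""
    path = Path(path)
    triplets: set[Triplet] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns, found {len(fields)}")
            if lineno == 1 and fields[0].lower() in {"lncrna", "lnc"}:
                continue
            triplets.add(Triplet(*(f.strip() for f in fields)))
    return triplets
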