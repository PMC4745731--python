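"""Signed pathway definitions and drug-target maps.

A pathway is a set of member proteins, each tagged with an activator/repressor
role (ARR, +1 or -1), plus a pathway-level flag (AMCF, +1 or -1) recording
whether activating the pathway promotes or inhibits mitosis and cell survival.
A drug-target map associates each drug with the set of proteins it inhibits.
Membership of a protein in a pathway is the node involvement index (NII);
it is represented implicitly by the member dictionaries.

Gene identifiers are HGNC-style symbols, case-folded to upper case at ingest;
all downstream matching is exact string equality after folding.
"""

from __future__ import annotations

import io
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pascore.errors import ParseError, ValidationError

__all__ = [
    "PathwayDefinition",
    "PathwayDB",
    "DrugTargetMap",
    "CoverageReport",
    "read_pathway_db",
    "write_pathway_db",
    "read_drug_targets",
    "write_drug_targets",
    "validate_db",
]

_VALID_SIGNS = (-1, 1)


def _fold(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class PathwayDefinition:
    """One pathway: its members with ARR roles and its AMCF flag.

    Parameters
    ----------
    pathway_id
        Unique identifier of the pathway.
    members
        Mapping gene symbol -> ARR role, +1 for an activator of signalling
        through the pathway, -1 for a repressor.
    amcf
        +1 if activation of the pathway promotes mitosis, -1 if it inhibits it.
    """

    pathway_id: str
    members: Mapping[str, int]
    amcf: int = 1

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValidationError("pathway_id must be non-empty")
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id!r}: members empty")
        folded: "OrderedDict[str, int]" = OrderedDict()
        for gene, arr in self.members.items():
            g = _fold(gene)
            if not g:
                raise ValidationError(f"pathway {self.pathway_id!r}: empty gene symbol")
            if g in folded:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: duplicate member {g!r}"
                )
            if arr not in _VALID_SIGNS:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: ARR for {g!r} must be -1 or +1, got {arr!r}"
                )
            folded[g] = int(arr)
        object.__setattr__(self, "members", folded)
        if self.amcf not in _VALID_SIGNS:
            raise ValidationError(
                f"pathway {self.pathway_id!r}: AMCF must be -1 or +1, got {self.amcf!r}"
            )
        object.__setattr__(self, "amcf", int(self.amcf))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.members)

    def arr(self, gene: str) -> int:
        return self.members[_fold(gene)]

    def contains(self, gene: str) -> bool:
        """Node involvement index: 1 iff the gene is a pathway member."""
        return _fold(gene) in self.members

    def flip_roles(self) -> "PathwayDefinition":
        """Return a copy with every ARR negated (used by sign-law tests)."""
        return PathwayDefinition(
            self.pathway_id, {g: -a for g, a in self.members.items()}, self.amcf
        )


class PathwayDB:
    """Ordered collection of pathways with a gene -> pathway index."""

    def __init__(self, pathways: Iterable[PathwayDefinition]):
        self.pathways: list[PathwayDefinition] = list(pathways)
        if not self.pathways:
            raise ValidationError("no pathways")
        seen: set[str] = set()
        for pw in self.pathways:
            if pw.pathway_id in seen:
                raise ValidationError(f"duplicate pathway_id {pw.pathway_id!r}")
            seen.add(pw.pathway_id)
        self._by_id = {pw.pathway_id: pw for pw in self.pathways}
        self.gene_index: dict[str, list[str]] = self._build_gene_index()

    def _build_gene_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {}
        for pw in self.pathways:
            for gene in pw.members:
                index.setdefault(gene, []).append(pw.pathway_id)
        return index

    @property
    def pathway_ids(self) -> list[str]:
        return [pw.pathway_id for pw in self.pathways]

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> PathwayDefinition:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self.pathways == other.pathways

    def pathways_for_gene(self, gene: str) -> list[str]:
        return self.gene_index.get(_fold(gene), [])


@dataclass(frozen=True)
class DrugTargetMap:
    """Drug -> set of target gene symbols (the drug-target index, DTI)."""

    targets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError("no drugs")
        folded: dict[str, frozenset[str]] = {}
        for drug, genes in self.targets.items():
            name = drug.strip()
            if not name:
                raise ValidationError("empty drug name")
            if name in folded:
                raise ValidationError(f"duplicate drug name {name!r}")
            gset = frozenset(_fold(g) for g in genes)
            if not gset or "" in gset:
                raise ValidationError(f"drug {name!r}: target set empty or blank")
            folded[name] = gset
        object.__setattr__(self, "targets", folded)

    @property
    def drugs(self) -> list[str]:
        return list(self.targets)

    def __getitem__(self, drug: str) -> frozenset[str]:
        return self.targets[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.targets

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _iter_data_lines(path: Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_sign(text: str, what: str, path: Path, lineno: int) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} must be an integer, got {text!r}")
    if value not in _VALID_SIGNS:
        raise ValidationError(f"{path}:{lineno}: {what} must be -1 or +1, got {value}")
    return value


def read_pathway_db(
    path: str | Path,
    format: str = "native_tsv",
    roles_path: str | Path | None = None,
    amcf_path: str | Path | None = None,
) -> PathwayDB:
    """Read a pathway database.

    ``native_tsv`` is a 4-column file ``pathway_id<TAB>amcf<TAB>gene<TAB>arr``
    with one member per row; ``#`` lines are comments.  ``gmt`` is the
    standard gene-set format; every member defaults to ARR = +1 and every
    pathway to AMCF = +1 unless a sidecar roles / AMCF file overrides them.
    """
    path = Path(path)
    if format == "native_tsv":
        db = _read_native_tsv(path)
    elif format == "gmt":
        db = _read_gmt(path)
    else:
        raise ValueError(f"unknown pathway format {format!r}")
    if roles_path is not None or amcf_path is not None:
        db = _apply_sidecars(db, roles_path, amcf_path)
    return db


def _read_native_tsv(path: Path) -> PathwayDB:
    order: list[str] = []
    amcf: dict[str, int] = {}
    members: dict[str, OrderedDict[str, int]] = {}
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
            )
        pid, amcf_s, gene, arr_s = (p.strip() for p in parts)
        if not pid or not gene:
            raise ParseError(f"{path}:{lineno}: empty pathway_id or gene field")
        a = _parse_sign(amcf_s, "AMCF", path, lineno)
        arr = _parse_sign(arr_s, "ARR", path, lineno)
        if pid not in members:
            order.append(pid)
            members[pid] = OrderedDict()
            amcf[pid] = a
        elif amcf[pid] != a:
            raise ValidationError(
                f"{path}:{lineno}: pathway {pid!r} has conflicting AMCF values"
            )
        g = _fold(gene)
        if g in members[pid]:
            raise ValidationError(
                f"{path}:{lineno}: duplicate member {g!r} in pathway {pid!r}"
            )
        members[pid][g] = arr
    if not order:
        raise ParseError(f"{path}: no pathways")
    return PathwayDB(
        PathwayDefinition(pid, members[pid], amcf[pid]) for pid in order
    )


def _read_gmt(path: Path) -> PathwayDB:
    defs: list[PathwayDefinition] = []
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
            )
        pid = parts[0].strip()
        genes = [g for g in (p.strip() for p in parts[2:]) if g]
        if not pid or not genes:
            raise ParseError(f"{path}:{lineno}: empty set name or gene list")
        members = OrderedDict()
        for g in genes:
            members.setdefault(_fold(g), 1)
        defs.append(PathwayDefinition(pid, members, 1))
    if not defs:
        raise ParseError(f"{path}: no pathways")
    return PathwayDB(defs)


def _apply_sidecars(
    db: PathwayDB,
    roles_path: str | Path | None,
    amcf_path: str | Path | None,
) -> PathwayDB:
    roles: dict[tuple[str, str], int] = {}
    if roles_path is not None:
        rp = Path(roles_path)
        for lineno, line in _iter_data_lines(rp):
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{rp}:{lineno}: expected pathway<TAB>gene<TAB>arr")
            pid, gene, arr_s = (p.strip() for p in parts)
            roles[(pid, _fold(gene))] = _parse_sign(arr_s, "ARR", rp, lineno)
    amcfs: dict[str, int] = {}
    if amcf_path is not None:
        ap = Path(amcf_path)
        for lineno, line in _iter_data_lines(ap):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{ap}:{lineno}: expected pathway<TAB>amcf")
            pid, amcf_s = (p.strip() for p in parts)
            amcfs[pid] = _parse_sign(amcf_s, "AMCF", ap, lineno)
    rebuilt = []
    for pw in db:
        members = OrderedDict(
            (g, roles.get((pw.pathway_id, g), arr)) for g, arr in pw.members.items()
        )
        rebuilt.append(
            PathwayDefinition(pw.pathway_id, members, amcfs.get(pw.pathway_id, pw.amcf))
        )
    return PathwayDB(rebuilt)


def write_pathway_db(db: PathwayDB, path: str | Path) -> None:
    """Write a PathwayDB in the native 4-column TSV dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pathway_id\tamcf\tgene_symbol\tarr\n")
        for pw in db:
            for gene, arr in pw.members.items():
                fh.write(f"{pw.pathway_id}\t{pw.amcf:+d}\t{gene}\t{arr:+d}\n")


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a two-column ``drug<TAB>gene`` TSV; multi-row drugs are unioned.

    A header row is tolerated: a first line whose second field is literally
    ``gene``, ``gene_symbol`` or ``target`` (any case) is skipped.
    """
    path = Path(path)
    targets: dict[str, set[str]] = {}
    order: list[str] = []
    first = True
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected drug<TAB>gene, got {len(parts)} fields"
            )
        drug, gene = (p.strip() for p in parts)
        if first:
            first = False
            if gene.lower() in {"gene", "gene_symbol", "target"}:
                continue
        if not drug or not gene:
            raise ParseError(f"{path}:{lineno}: empty drug or gene field")
        if drug not in targets:
            targets[drug] = set()
            order.append(drug)
        targets[drug].add(_fold(gene))
    if not order:
        raise ParseError(f"{path}: no drugs")
    return DrugTargetMap({d: frozenset(targets[d]) for d in order})


def write_drug_targets(dtm: DrugTargetMap, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tgene_symbol\n")
        for drug in dtm.drugs:
            for gene in sorted(dtm[drug]):
                fh.write(f"{drug}\t{gene}\n")


# ---------------------------------------------------------------------------
# Coverage report
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    """How well a gene universe covers the pathway DB and drug targets.

    ``pathway_coverage`` maps pathway_id -> fraction of members measured;
    ``inert_targets`` maps drug -> targets that belong to no pathway (those
    targets can never contribute to a drug score); ``unmeasured_targets``
    maps drug -> targets absent from the gene universe.
    """

    pathway_coverage: dict[str, float] = field(default_factory=dict)
    inert_targets: dict[str, list[str]] = field(default_factory=dict)
    unmeasured_targets: dict[str, list[str]] = field(default_factory=dict)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("pathway coverage (fraction of members in gene universe):\n")
        for pid, frac in self.pathway_coverage.items():
            buf.write(f"  {pid}\t{frac:.3f}\n")
        buf.write("inert targets (in no pathway; contribute nothing to DS):\n")
        for drug, genes in self.inert_targets.items():
            if genes:
                buf.write(f"  {drug}\t{','.join(genes)}\n")
        buf.write("unmeasured targets (absent from expression):\n")
        for drug, genes in self.unmeasured_targets.items():
            if genes:
                buf.write(f"  {drug}\t{','.join(genes)}\n")
        return buf.getvalue()


def validate_db(
    db: PathwayDB, dtm: DrugTargetMap | None, genes: Iterable[str]
) -> CoverageReport:
    """Report pathway coverage by a gene universe and inert drug targets."""
    universe = {_fold(g) for g in genes}
    report = CoverageReport()
    for pw in db:
        measured = sum(1 for g in pw.members if g in universe)
        report.pathway_coverage[pw.pathway_id] = measured / len(pw.members)
    if dtm is not None:
        for drug in dtm.drugs:
            tset = dtm[drug]
            report.inert_targets[drug] = sorted(
                t for t in tset if not db.pathways_for_gene(t)
            )
            report.unmeasured_targets[drug] = sorted(
                t for t in tset if t not in universe
            )
    return report
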