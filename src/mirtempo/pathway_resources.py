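"""Pathway gene sets (GMT) and miRNA-target databases from local snapshots.

Three target databases are supported: two predictive (TargetScan, miRDB,
both seed-complementarity based) and one functional (miRTarBase), from
which interactions whose functional support is labeled "weak" are removed
by default.  All resources are read from local files; the package performs
no network access.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

NAMESPACES = ("entrez", "ensembl")
PREDICTIVE_DBS = ("targetscan", "mirdb")
FUNCTIONAL_DBS = ("mirtarbase",)
ALL_DBS = PREDICTIVE_DBS + FUNCTIONAL_DBS

WEAK_PATTERN = re.compile("weak", re.IGNORECASE)


class ResourceError(ValueError):
    """Malformed GMT or target-database file."""


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class PathwaySet:
    """Named gene sets in a single declared identifier namespace."""

    pathways: tuple[Pathway, ...]
    namespace: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ResourceError(f"namespace must be one of {NAMESPACES}")
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ResourceError("pathway IDs are not unique")
        for p in self.pathways:
            if not p.members:
                raise ResourceError(f"pathway {p.pathway_id} has no members")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]


@dataclass(frozen=True)
class TargetDB:
    """A miRNA->mRNA target table: set of (mirna label, target gene ID) pairs.

    ``kind`` is 'predictive' (TargetScan, miRDB) or 'functional'
    (miRTarBase); only functional databases carry evidence strings, and
    after loading with the weak filter none of the retained pairs has
    weak-labeled support.
    """

    name: str
    kind: str
    pairs: frozenset[tuple[str, str]]
    evidence: dict = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


def read_gmt(path, namespace: str) -> PathwaySet:
    """Parse a GMT file: per line ``name<TAB>pathway_id<TAB>gene...``.

    Duplicate genes within a line are collapsed (set semantics).  Lines
    with fewer than three fields are a hard error.
    """
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ResourceError(f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)")
            name, pathway_id = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            pathways.append(Pathway(pathway_id, name, members))
    if not pathways:
        logger.warning("%s: empty GMT file", path)
    return PathwaySet(tuple(pathways), namespace)


def write_gmt(pathways: PathwaySet, path) -> None:
    """Write GMT with members sorted for byte-determinism."""
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.name, p.pathway_id, *sorted(p.members)]) + "\n")


def read_target_db(
    path,
    name: str,
    drop_weak: bool = True,
    weak_pattern: re.Pattern | str = WEAK_PATTERN,
) -> TargetDB:
    """Read a tab-separated target table ``mirna<TAB>target[<TAB>evidence]``.

    For miRTarBase (the functional database) the evidence column is
    mandatory and, with ``drop_weak`` (the default), every pair whose
    evidence matches ``weak_pattern`` (substring 'weak', case-insensitive)
    is removed.  Predictive databases ignore the flag.
    """
    if name not in ALL_DBS:
        raise ResourceError(f"unknown database {name!r}; expected one of {ALL_DBS}")
    kind = "functional" if name in FUNCTIONAL_DBS else "predictive"
    if isinstance(weak_pattern, str):
        weak_pattern = re.compile(weak_pattern, re.IGNORECASE)

    pairs: set[tuple[str, str]] = set()
    evidence: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_evidence = len(header) >= 3
        if kind == "functional" and not has_evidence:
            raise ResourceError(f"{path}: evidence column required for {name}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ResourceError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            mirna, target = fields[0], fields[1]
            ev = fields[2] if len(fields) >= 3 else ""
            if kind == "functional":
                if drop_weak and weak_pattern.search(ev):
                    continue
                evidence[(mirna, target)] = ev
            pairs.add((mirna, target))
    if kind == "predictive":
        evidence = {}
    return TargetDB(name, kind, frozenset(pairs), evidence)
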