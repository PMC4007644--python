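"""Ortholog tables: the gene-level alignment substrate between strains.

An ortholog group collects the genes across strains that descend from a
common ancestor.  The table is the bridge for every cross-strain
operation here: template-based model derivation, core-model gene
intersection, and gene-aligned network comparison.

On disk the table is tab-delimited: a header row with a ``group`` column
followed by one column per strain; each cell holds the strain's member
gene ids (separated by a configurable delimiter, ``;`` by default),
``-`` or empty for absence.  A ``^`` suffix marks a pseudogene — a gene
fragment that is present in the genome but non-functional, and therefore
treated as absent for all functional purposes while remaining visible in
the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

__all__ = ["Member", "OrthologTable", "read_ortholog_table", "OrthologTableError"]

ABSENT = "-"
PSEUDO_SUFFIX = "^"


class OrthologTableError(ValueError):
    """Malformed ortholog table (duplicate members, bad header, ...)."""


@dataclass(frozen=True)
class Member:
    gene: str
    pseudogene: bool = False


class OrthologTable:
    """Strain x ortholog-group membership with pseudogene flags."""

    def __init__(
        self,
        strains: Sequence[str],
        groups: Mapping[str, Mapping[str, Sequence[Member]]],
    ) -> None:
        self.strains = list(strains)
        self.groups: Dict[str, Dict[str, Tuple[Member, ...]]] = {}
        seen: Dict[str, Dict[str, str]] = {s: {} for s in self.strains}
        for gid, per_strain in groups.items():
            row: Dict[str, Tuple[Member, ...]] = {}
            for strain, members in per_strain.items():
                if strain not in seen:
                    raise OrthologTableError(
                        f"group {gid!r} references unknown strain {strain!r}"
                    )
                members = tuple(members)
                for mem in members:
                    prev = seen[strain].get(mem.gene)
                    if prev is not None and prev != gid:
                        raise OrthologTableError(
                            f"gene {mem.gene!r} of strain {strain!r} appears in "
                            f"groups {prev!r} and {gid!r}"
                        )
                    seen[strain][mem.gene] = gid
                if members:
                    row[strain] = members
            self.groups[gid] = row

    # -- membership queries ---------------------------------------------

    def functional_members(self, gid: str, strain: str) -> List[str]:
        """Non-pseudogene member gene ids of *gid* in *strain*."""
        return [
            m.gene for m in self.groups.get(gid, {}).get(strain, ())
            if not m.pseudogene
        ]

    def has_functional_member(self, gid: str, strain: str) -> bool:
        return bool(self.functional_members(gid, strain))

    def gene_to_group(self, strain: str,
                      functional_only: bool = True) -> Dict[str, str]:
        out = {}
        for gid, row in self.groups.items():
            for mem in row.get(strain, ()):
                if functional_only and mem.pseudogene:
                    continue
                out[mem.gene] = gid
        return out

    def mapping(self, from_strain: str, to_strain: str) -> Dict[str, List[str]]:
        """Gene translation map between strains through shared groups.

        Every functional gene of *from_strain* maps to the (possibly
        empty) list of functional co-orthologs in *to_strain*.
        """
        out = {}
        for gid, row in self.groups.items():
            targets = self.functional_members(gid, to_strain)
            for mem in row.get(from_strain, ()):
                if not mem.pseudogene:
                    out[mem.gene] = list(targets)
        return out

    def groups_conserved_in(self, strains: Sequence[str]) -> List[str]:
        """Group ids with a functional member in every listed strain."""
        return [
            gid for gid in self.groups
            if all(self.has_functional_member(gid, s) for s in strains)
        ]

    def shared_groups(self, strain_a: str, strain_b: str) -> List[str]:
        return self.groups_conserved_in([strain_a, strain_b])

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path: str, member_delimiter: str = ";") -> None:
        with open(path, "w") as fh:
            fh.write("group\t" + "\t".join(self.strains) + "\n")
            for gid in sorted(self.groups):
                cells = []
                for strain in self.strains:
                    members = self.groups[gid].get(strain, ())
                    if not members:
                        cells.append(ABSENT)
                    else:
                        cells.append(member_delimiter.join(
                            m.gene + (PSEUDO_SUFFIX if m.pseudogene else "")
                            for m in members
                        ))
                fh.write(gid + "\t" + "\t".join(cells) + "\n")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OrthologTable)
            and self.strains == other.strains
            and self.groups == other.groups
        )


def read_ortholog_table(path: str, member_delimiter: str = ";") -> OrthologTable:
    """Parse a tab-delimited ortholog table.

    Raises :class:`OrthologTableError` (with the row number) when a gene
    id appears in more than one group for the same strain.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0].lower() != "group":
            raise OrthologTableError(
                f"{path}: first header column must be 'group', got {header[:1]}"
            )
        strains = header[1:]
        if not strains:
            raise OrthologTableError(f"{path}: no strain columns")
        groups: Dict[str, Dict[str, List[Member]]] = {}
        seen: Dict[str, Dict[str, str]] = {s: {} for s in strains}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(strains) + 1:
                raise OrthologTableError(
                    f"{path}:{lineno}: expected {len(strains) + 1} columns, "
                    f"got {len(cells)}"
                )
            gid = cells[0]
            if gid in groups:
                raise OrthologTableError(f"{path}:{lineno}: duplicate group {gid!r}")
            row: Dict[str, List[Member]] = {}
            for strain, cell in zip(strains, cells[1:]):
                cell = cell.strip()
                if not cell or cell == ABSENT:
                    continue
                members = []
                for token in cell.split(member_delimiter):
                    token = token.strip()
                    if not token:
                        continue
                    pseudo = token.endswith(PSEUDO_SUFFIX)
                    gene = token[:-1] if pseudo else token
                    prev = seen[strain].get(gene)
                    if prev is not None:
                        raise OrthologTableError(
                            f"{path}:{lineno}: gene {gene!r} of strain "
                            f"{strain!r} already in group {prev!r}"
                        )
                    seen[strain][gene] = gid
                    members.append(Member(gene, pseudo))
                if members:
                    row[strain] = members
            groups[gid] = row
    return OrthologTable(strains, groups)
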