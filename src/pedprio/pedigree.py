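"""Pedigree model: PED parsing, validation, and role classification.

The segregation analysis distinguishes four (partially overlapping) role
sets within a disease pedigree:

* **affected** — members with an affected phenotype; under the assumed
  dominant model every one of them must carry the causal allele.
* **unaffected blood members** — unaffected members of the family lineage.
* **marry-ins** — founders who joined the family by marriage; the causal
  allele is assumed to have entered through the founding couple, so a
  variant carried by a marry-in cannot be the family's causal variant.
* **obligate carriers** — unaffected blood members who, by position in the
  pedigree, must carry the causal allele under the dominant model (an
  unaffected parent of affected children whose co-parent is a marry-in);
  they are exempted from the unaffected-carrier penalty and required to
  share the causal variant.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Union

from .errors import PedigreeFormatError, PedigreeStructureError

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
AFFECTION_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member, as described by a 6-column PED row."""

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affected: str = "unknown"

    @property
    def is_founder(self) -> bool:
        """True when neither parent is recorded in the pedigree."""
        return self.father_id is None and self.mother_id is None

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(p for p in (self.father_id, self.mother_id) if p is not None)


@dataclass(frozen=True)
class RolePartition:
    """Disjoint partition of members with known status, plus the unknowns.

    ``affected | unaffected_blood | marry_in | unknown_status`` covers all
    members; ``obligate_carrier`` is a subset of ``unaffected_blood``.
    """

    affected: frozenset[str]
    unaffected_blood: frozenset[str]
    marry_in: frozenset[str]
    unknown_status: frozenset[str]
    obligate_carrier: frozenset[str] = frozenset()


class Pedigree:
    """A validated single-family pedigree."""

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeFormatError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid in ind.parent_ids:
                if pid not in self.members:
                    raise PedigreeStructureError(
                        f"individual {ind.id!r} references parent {pid!r} "
                        "who is not in the pedigree"
                    )
        # acyclicity: walk ancestors of each member
        for start in self.members:
            stack, seen = [start], set()
            while stack:
                cur = stack.pop()
                for pid in self.members[cur].parent_ids:
                    if pid == start:
                        raise PedigreeStructureError(
                            f"parentage cycle involving individual {start!r}"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    # -- basic structure ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.members)

    @property
    def founders(self) -> frozenset[str]:
        return frozenset(i.id for i in self.members.values() if i.is_founder)

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            ind
            for ind in self.members.values()
            if parent_id in ind.parent_ids
        ]

    def co_parent(self, parent_id: str, child: Individual) -> Optional[str]:
        """The other recorded parent of *child*, or None."""
        others = [p for p in child.parent_ids if p != parent_id]
        return others[0] if others else None

    # -- lineage partition ----------------------------------------------

    def structural_blood(self) -> frozenset[str]:
        """Members of the family lineage (everyone who is not a marry-in).

        The founding couple — a pair of founders who are co-parents of one
        another's children — seeds the lineage; descent closes it.  Founders
        outside any founding couple who have a child with a lineage member
        are marry-ins.  Isolated/childless founders are kept in the lineage.
        """
        if not self.founders:
            raise PedigreeStructureError("pedigree has no founders")
        couples = set()
        for ind in self.members.values():
            if ind.father_id is not None and ind.mother_id is not None:
                couples.add(frozenset((ind.father_id, ind.mother_id)))
        founding = {
            m for pair in couples if all(p in self.founders for p in pair) for m in pair
        }
        blood = set(founding) if founding else set(self.founders)
        changed = True
        while changed:
            changed = False
            for ind in self.members.values():
                if ind.id not in blood and any(p in blood for p in ind.parent_ids):
                    blood.add(ind.id)
                    changed = True
        # childless or isolated founders: no marriage link, keep as lineage
        for f in self.founders:
            if f not in blood and not self.children_of(f):
                blood.add(f)
        return frozenset(blood)

    def structural_marry_ins(self) -> frozenset[str]:
        blood = self.structural_blood()
        out = set()
        for f in self.founders - blood:
            for child in self.children_of(f):
                co = self.co_parent(f, child)
                if co is not None and co in blood:
                    out.add(f)
                    break
        return frozenset(out)


def parse_ped(source: Union[str, os.PathLike, io.TextIOBase]) -> Pedigree:
    """Parse a 6-column PED file into a validated :class:`Pedigree`.

    Columns: family, individual, father, mother, sex (1/2/0), phenotype
    (2=affected, 1=unaffected, 0 or -9=unknown).  ``0`` marks a missing
    parent.  Exactly one family per file is supported.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            return parse_ped(fh)

    family_id = None
    members: list[Individual] = []
    for lineno, raw in enumerate(source, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeFormatError(
                f"PED line {lineno}: expected 6 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        fam, iid, fid, mid, sex, pheno = fields[:6]
        if family_id is None:
            family_id = fam
        elif fam != family_id:
            raise PedigreeFormatError(
                f"PED line {lineno}: multiple family ids ({family_id!r}, {fam!r})"
            )
        if pheno not in AFFECTION_CODES:
            raise PedigreeFormatError(
                f"PED line {lineno}: unknown affection code {pheno!r}"
            )
        members.append(
            Individual(
                id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=SEX_CODES.get(sex, "unknown"),
                affected=AFFECTION_CODES[pheno],
            )
        )
    if family_id is None:
        raise PedigreeFormatError("empty PED input")
    return Pedigree(family_id, members)


def write_ped(ped: Pedigree, dest: Union[str, os.PathLike, io.TextIOBase]) -> None:
    """Write a pedigree back to 6-column PED text (inverse of parse_ped)."""
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w") as fh:
            write_ped(ped, fh)
            return
    sex_rev = {"male": "1", "female": "2", "unknown": "0"}
    aff_rev = {"affected": "2", "unaffected": "1", "unknown": "0"}
    for ind in ped.members.values():
        dest.write(
            "\t".join(
                (
                    ped.family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    sex_rev[ind.sex],
                    aff_rev[ind.affected],
                )
            )
            + "\n"
        )


def classify_roles(ped: Pedigree) -> RolePartition:
    """Partition members into affected / unaffected-blood / marry-in roles.

    Marry-ins are structural (lineage-based) but only listed in the
    marry-in role set when their status is known-unaffected; an affected
    member always lands in ``affected``.  Members of unknown status take
    part in no filter role set.
    """
    marry_struct = ped.structural_marry_ins()
    affected, unaff_blood, marry_in, unknown = set(), set(), set(), set()
    for ind in ped.members.values():
        if ind.affected == "affected":
            affected.add(ind.id)
        elif ind.affected == "unknown":
            unknown.add(ind.id)
        elif ind.id in marry_struct:
            marry_in.add(ind.id)
        else:
            unaff_blood.add(ind.id)
    return RolePartition(
        affected=frozenset(affected),
        unaffected_blood=frozenset(unaff_blood),
        marry_in=frozenset(marry_in),
        unknown_status=frozenset(unknown),
    )


def infer_obligate_carriers(
    ped: Pedigree,
    model: str = "dominant",
    overrides: Iterable[str] = (),
) -> frozenset[str]:
    """Infer unaffected blood members who must carry the causal allele.

    Under a dominant within-family model the allele cannot have entered
    through a marry-in, so an unaffected blood member with at least one
    affected child whose other parent is a marry-in is an obligate
    carrier.  ``overrides`` adds user-designated ids (validated to be
    unaffected non-marry-ins).
    """
    if model != "dominant":
        raise ValueError(f"unsupported inheritance model {model!r}")
    roles = classify_roles(ped)
    marry_struct = ped.structural_marry_ins()
    out: set[str] = set()
    for bid in roles.unaffected_blood:
        for child in ped.children_of(bid):
            if child.affected != "affected":
                continue
            co = ped.co_parent(bid, child)
            if co is not None and co in marry_struct:
                out.add(bid)
                break
    for oid in overrides:
        if oid not in ped.members:
            raise PedigreeStructureError(
                f"obligate-carrier override {oid!r} not in pedigree"
            )
        if oid in roles.affected or oid in marry_struct:
            raise PedigreeStructureError(
                f"obligate-carrier override {oid!r} is affected or a marry-in"
            )
        out.add(oid)
    return frozenset(out)


def classify_roles_with_carriers(
    ped: Pedigree, overrides: Iterable[str] = ()
) -> RolePartition:
    """Full role partition including inferred+overridden obligate carriers."""
    base = classify_roles(ped)
    carriers = infer_obligate_carriers(ped, overrides=overrides)
    return RolePartition(
        affected=base.affected,
        unaffected_blood=base.unaffected_blood,
        marry_in=base.marry_in,
        unknown_status=base.unknown_status,
        obligate_carrier=carriers,
    )
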