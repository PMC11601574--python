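"""HLA/KIR immunogenetics: KIR-ligand profiles, NK-cell education, missing-self.

Class I HLA allotypes carry serologically defined epitopes that serve as
ligands for inhibitory killer-cell immunoglobulin-like receptors (KIRs):
Bw4 for KIR3DL1, C1 for KIR2DL2/L3, C2 for KIR2DL1, and A3/A11 for KIR3DL2.
NK cells expressing an inhibitory receptor whose cognate ligand is encoded
in the subject's own HLA genotype are *educated* (licensed): they respond
more vigorously when the inhibitory interaction is released.  In kidney
transplantation a recipient whose donor encodes fewer copies of a ligand
than the recipient ("missing self", here Bw4 loss) releases the recipient's
educated NK cells from inhibition by the graft.

The allele -> epitope mapping ships with the package as a versioned CSV
built from the published epitope motif definitions (residues 77-83 for
Bw4/Bw6, the residue-80 C1/C2 dimorphism, and the A*03/A*11 KIR3DL2
epitope).  Lookup is exact at 2-field resolution first, then falls back to
the 1-field allele group with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: inhibitory KIR genes with defined HLA class I ligands
KIR_GENES = ("KIR3DL1", "KIR3DL2", "KIR2DL1", "KIR2DL2", "KIR2DL3")

#: receptor labels used in education assignments (KIR2DL2 and KIR2DL3 share
#: the C1 ligand and are merged, matching the conventional "KIR2DL2/L3" label)
RECEPTOR_NKG2A = "NKG2A"
RECEPTOR_KIR3DL1 = "KIR3DL1"
RECEPTOR_KIR2DL1 = "KIR2DL1"
RECEPTOR_KIR2DL2L3 = "KIR2DL2/L3"
RECEPTOR_KIR3DL2 = "KIR3DL2"

_ALLELE_RE = re.compile(r"^([ABC])\*(\d+)(?::(\d+))?$")

# alleles already warned about via the 1-field fallback (warn once each)
_warned_fallback: set[str] = set()


class AlleleParseError(ValueError):
    """Allele string does not match ``<locus>*<group>:<protein>``."""


class AlleleLookupError(KeyError):
    """Allele absent from the epitope table at 2- and 1-field resolution."""


@dataclass(frozen=True)
class HlaGenotype:
    """Class I HLA genotype at 2-field resolution.

    ``alleles`` maps each locus ("A", "B", "C") to exactly two allele names;
    homozygotes repeat the allele.
    """

    subject_id: str
    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for locus in ("A", "B", "C"):
            pair = self.alleles.get(locus)
            if pair is None or len(pair) != 2:
                raise ValueError(
                    f"{self.subject_id}: locus {locus} needs exactly 2 alleles"
                )
            for allele in pair:
                m = _ALLELE_RE.match(allele)
                if m is None:
                    raise AlleleParseError(
                        f"{self.subject_id}: malformed allele {allele!r}"
                    )
                if m.group(1) != locus:
                    raise AlleleParseError(
                        f"{self.subject_id}: allele {allele!r} listed under locus {locus}"
                    )


@dataclass(frozen=True)
class KirGenotype:
    """Presence/absence of the inhibitory KIR genes."""

    subject_id: str
    kir3dl1: bool
    kir3dl2: bool
    kir2dl1: bool
    kir2dl2: bool
    kir2dl3: bool

    def has(self, gene: str) -> bool:
        return bool(getattr(self, gene.lower()))


@dataclass(frozen=True)
class LigandProfile:
    """KIR-ligand copy counts derived from one HLA genotype.

    ``bw4_copies`` counts Bw4-motif alleles over HLA-B plus the Bw4-bearing
    HLA-A allotypes (A*23/A*24/A*32), so it ranges 0-4.  ``c1_copies`` and
    ``c2_copies`` partition the two HLA-C alleles; the rare C1-bearing HLA-B
    alleles (B*46:01, B*73:01) are tracked separately in ``b_c1_copies`` so
    the HLA-C partition invariant stays exact.
    """

    bw4_copies: int
    c1_copies: int
    c2_copies: int
    a3a11_present: bool
    b_c1_copies: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bw4_copies <= 4:
            raise ValueError(f"bw4_copies out of range: {self.bw4_copies}")
        if self.c1_copies + self.c2_copies != 2:
            raise ValueError("HLA-C alleles must partition into C1/C2 (2 total)")

    @property
    def total_c1(self) -> int:
        return self.c1_copies + self.b_c1_copies


@dataclass(frozen=True)
class EducationAssignment:
    """Receptors through which a subject's NK cells are educated."""

    subject_id: str
    educated_receptors: frozenset[str]


class MissingSelfCategory(str, Enum):
    BW4_LOSS = "BW4_LOSS"
    NO_LOSS = "NO_LOSS"


@dataclass(frozen=True)
class MissingSelfCall:
    """Donor/recipient Bw4 missing-self categorization."""

    pair_id: str
    category: MissingSelfCategory
    recipient_bw4: int
    donor_bw4: int
    recipient_has_kir3dl1: bool


def load_epitope_table() -> dict[str, str]:
    """Load the bundled allele -> epitope mapping.

    Returns a dict keyed by allele name (1-field groups and 2-field
    exceptions) with epitope values in
    {"bw4", "bw6", "c1", "c2", "a3a11", "none"}.
    """
    with resources.files("nkgraft.data").joinpath("kir_ligand_epitopes.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    return dict(zip(table["allele"], table["epitope"]))


def _lookup_epitope(allele: str, epitope_table: Mapping[str, str]) -> str:
    m = _ALLELE_RE.match(allele)
    if m is None:
        raise AlleleParseError(f"malformed allele {allele!r}")
    if allele in epitope_table:
        return epitope_table[allele]
    group = f"{m.group(1)}*{m.group(2)}"
    if group in epitope_table:
        if allele not in _warned_fallback:
            _warned_fallback.add(allele)
            logger.warning("allele %s not in epitope table; using 1-field "
                           "group %s", allele, group)
        return epitope_table[group]
    raise AlleleLookupError(f"allele {allele} not in epitope table "
                            f"(nor its 1-field group {group})")


def ligand_profile(genotype: HlaGenotype,
                   epitope_table: Mapping[str, str] | None = None) -> LigandProfile:
    """Map an HLA genotype to its KIR-ligand copy counts.

    Bw4 is counted across HLA-B Bw4-motif alleles and the Bw4-bearing HLA-A
    allotypes; every HLA-C allele contributes to C1 or C2; ``a3a11_present``
    is true iff any A*03 or A*11 allele is carried.

    Raises
    ------
    AlleleLookupError
        if an allele is absent from the table at both resolutions.
    AlleleParseError
        if an allele string is malformed.
    """
    if epitope_table is None:
        epitope_table = load_epitope_table()
    bw4 = 0
    c1 = 0
    c2 = 0
    b_c1 = 0
    a3a11 = False
    for allele in genotype.alleles["A"]:
        ep = _lookup_epitope(allele, epitope_table)
        if ep == "bw4":
            bw4 += 1
        elif ep == "a3a11":
            a3a11 = True
    for allele in genotype.alleles["B"]:
        ep = _lookup_epitope(allele, epitope_table)
        if ep == "bw4":
            bw4 += 1
        elif ep == "c1":
            b_c1 += 1
    for allele in genotype.alleles["C"]:
        ep = _lookup_epitope(allele, epitope_table)
        if ep == "c1":
            c1 += 1
        elif ep == "c2":
            c2 += 1
        else:
            raise AlleleLookupError(
                f"HLA-C allele {allele} maps to {ep!r}; every HLA-C allele "
                "must be C1 or C2")
    return LigandProfile(bw4_copies=bw4, c1_copies=c1, c2_copies=c2,
                         a3a11_present=a3a11, b_c1_copies=b_c1)


def assign_education(profile: LigandProfile, kir: KirGenotype,
                     *, include_nkg2a: bool = True) -> EducationAssignment:
    """Assign educated inhibitory receptors from ligand profile + KIR genes.

    A KIR educates only if the gene is present *and* its cognate ligand is
    encoded: KIR3DL1 needs >= 1 Bw4 copy, KIR2DL1 >= 1 C2, KIR2DL2/L3
    (either gene) >= 1 C1, KIR3DL2 an A*03 or A*11 allele.  NKG2A is treated
    as always educated because its ligand HLA-E is near-ubiquitously
    expressed; pass ``include_nkg2a=False`` to turn this off.
    """
    educated: set[str] = set()
    if include_nkg2a:
        educated.add(RECEPTOR_NKG2A)
    if kir.kir3dl1 and profile.bw4_copies >= 1:
        educated.add(RECEPTOR_KIR3DL1)
    if kir.kir2dl1 and profile.c2_copies >= 1:
        educated.add(RECEPTOR_KIR2DL1)
    if (kir.kir2dl2 or kir.kir2dl3) and profile.total_c1 >= 1:
        educated.add(RECEPTOR_KIR2DL2L3)
    if kir.kir3dl2 and profile.a3a11_present:
        educated.add(RECEPTOR_KIR3DL2)
    return EducationAssignment(subject_id=kir.subject_id,
                               educated_receptors=frozenset(educated))


def call_bw4_loss(recipient_profile: LigandProfile,
                  recipient_kir: KirGenotype,
                  donor_profile: LigandProfile,
                  pair_id: str | None = None) -> MissingSelfCall:
    """Categorize a donor/recipient pair for Bw4 missing-self.

    BW4_LOSS requires all of: the recipient carries >= 1 Bw4 copy, the
    recipient expresses KIR3DL1, and the donor carries strictly fewer Bw4
    copies than the recipient.  Pairs whose donor has equal or greater Bw4
    copy number, or whose recipient lacks KIR3DL1, are NO_LOSS.
    """
    r_bw4 = recipient_profile.bw4_copies
    d_bw4 = donor_profile.bw4_copies
    has_3dl1 = recipient_kir.kir3dl1
    loss = r_bw4 >= 1 and has_3dl1 and d_bw4 < r_bw4
    return MissingSelfCall(
        pair_id=pair_id if pair_id is not None else recipient_kir.subject_id,
        category=MissingSelfCategory.BW4_LOSS if loss else MissingSelfCategory.NO_LOSS,
        recipient_bw4=r_bw4,
        donor_bw4=d_bw4,
        recipient_has_kir3dl1=has_3dl1,
    )


def read_genotype_csv(path) -> tuple[list[HlaGenotype], list[KirGenotype]]:
    """Read genotypes from CSV with columns subject_id, A_1, A_2, B_1, B_2,
    C_1, C_2 and one 0/1 column per KIR gene."""
    table = pd.read_csv(path)
    hla: list[HlaGenotype] = []
    kir: list[KirGenotype] = []
    for _, row in table.iterrows():
        sid = str(row["subject_id"])
        hla.append(HlaGenotype(subject_id=sid, alleles={
            "A": (row["A_1"], row["A_2"]),
            "B": (row["B_1"], row["B_2"]),
            "C": (row["C_1"], row["C_2"]),
        }))
        kir.append(KirGenotype(subject_id=sid,
                               **{g.lower(): bool(int(row[g])) for g in KIR_GENES}))
    return hla, kir


def genotypes_to_frame(hla: Iterable[HlaGenotype],
                       kir: Iterable[KirGenotype]) -> pd.DataFrame:
    """Inverse of :func:`read_genotype_csv`: flatten genotypes to a table."""
    rows = []
    for h, k in zip(hla, kir):
        row = {"subject_id": h.subject_id}
        for locus in ("A", "B", "C"):
            row[f"{locus}_1"], row[f"{locus}_2"] = h.alleles[locus]
        for g in KIR_GENES:
            row[g] = int(k.has(g))
        rows.append(row)
    return pd.DataFrame(rows)
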