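"""Domain types for the SNP barcode panel and the reference registry.

A *barcode* is the ordered vector of categorical genotype calls a sample
produces on a fixed panel of biallelic SNP assays (default 32, three of them
Y-linked).  References — one barcode per patient, or per earliest available
xenograft passage when the patient sample is gone — live in a
:class:`ReferencePanel` against which every later sample is validated.

The default panel mirrors a commercial 32-assay human-identification
barcode chip: the three Y-chromosome assays and five assays with known
chromosomal locations carry their published vendor IDs; the remaining
assay IDs and all Y positions are illustrative placeholders.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import DuplicateReferenceError, InputFormatError, PanelMismatchError


class Category(str, enum.Enum):
    """Categorical genotype call of one biallelic assay."""

    HOM1 = "HOM1"   # homozygous allele 1 (red in heatmaps)
    HOM2 = "HOM2"   # homozygous allele 2 (blue)
    HET = "HET"     # heterozygous (green)
    NOAMP = "NOAMP" # no amplification (white)
    UNDET = "UNDET" # undetermined: weak signal or non-canonical channel ratio (white)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Calls that determine a genotype (as opposed to NOAMP/UNDET).
DETERMINED = frozenset({Category.HOM1, Category.HOM2, Category.HET})


class Sex(str, enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    INCONSISTENT = "INCONSISTENT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One call with a confidence in [0, 1].

    For NOAMP the quality quantifies the *absence-of-signal* evidence
    (how far below the amplification floor the endpoint sits), not a
    genotype confidence.
    """

    category: Category
    quality: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError(f"quality must be in [0,1], got {self.quality}")


@dataclass(frozen=True, slots=True)
class SNPAssay:
    """One biallelic TaqMan-style assay on the panel."""

    assay_id: str
    rs_id: str = ""
    chromosome: str = ""
    position: int = 1
    y_linked: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1 (1-based), got {self.position}")
        if self.y_linked and self.chromosome != "Y":
            raise ValueError(f"y_linked assay {self.assay_id} must have chromosome 'Y'")


@dataclass(frozen=True, slots=True)
class KaryotypeRegion:
    """A copy-number-altered genomic interval (1-based, inclusive ends).

    ``total_copies`` is the total copy number of the region,
    ``allele2_copies`` how many of those copies carry allele 2 at a SNP of
    interest (e.g. a heterozygous amplification to copy number 3 with two
    allele-2 copies gives per-allele dosage (1, 2)).
    """

    chromosome: str
    start: int
    end: int
    total_copies: int
    allele2_copies: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if not 0 <= self.allele2_copies <= self.total_copies:
            raise ValueError("allele2_copies must be in [0, total_copies]")

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


@dataclass(slots=True)
class SNPProfile:
    """One sample's barcode: an ordered map assay_id -> GenotypeCall."""

    sample_id: str
    calls: dict[str, GenotypeCall]
    passage_label: str = ""
    inferred_sex: Sex = Sex.UNKNOWN

    def category(self, assay_id: str) -> Category:
        return self.calls[assay_id].category

    def categories(self, assay_ids: list[str] | None = None) -> list[Category]:
        ids = assay_ids if assay_ids is not None else list(self.calls)
        return [self.calls[a].category for a in ids]


@dataclass(frozen=True, slots=True)
class ReferenceMeta:
    """Registry annotations for one reference profile."""

    patient_id: str
    sex: Sex = Sex.UNKNOWN
    karyotype_regions: tuple[KaryotypeRegion, ...] = ()
    provenance: str = "patient"  # "patient" | "earliest-passage"


@dataclass(slots=True)
class ReferencePanel:
    """The registry: the assay panel plus one reference barcode per PDX/patient."""

    assays: tuple[SNPAssay, ...]
    references: dict[str, SNPProfile] = field(default_factory=dict)
    metadata: dict[str, ReferenceMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.assay_id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate assay_id in panel")
        for rid, prof in self.references.items():
            self.check_profile(prof)

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]

    @property
    def y_assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays if a.y_linked]

    def check_profile(self, profile: SNPProfile) -> None:
        """Raise PanelMismatchError unless *profile* covers every assay exactly once."""
        missing = [a for a in self.assay_ids if a not in profile.calls]
        extra = [a for a in profile.calls if a not in set(self.assay_ids)]
        if missing or extra:
            raise PanelMismatchError(
                f"profile {profile.sample_id!r} does not cover the panel: "
                f"missing={missing} extra={extra}"
            )

    def cnv_assay_ids(self, reference_id: str) -> set[str]:
        """Assays overlapping a karyotype region annotated for *reference_id*."""
        meta = self.metadata.get(reference_id)
        if meta is None:
            return set()
        return {
            a.assay_id
            for a in self.assays
            for region in meta.karyotype_regions
            if region.contains(a.chromosome, a.position)
        }


class DuplicateProfileWarning(UserWarning):
    """A newly registered reference matches an existing one at all informative loci.

    Expected for diagnosis/relapse pairs from the same patient; fatal only if
    the two entries are supposed to be different patients.
    """


# --- default 32-assay panel -------------------------------------------------
# Three Y-linked assays and five assays with published chromosomal locations
# carry real vendor IDs; everything else is a synthetic placeholder.

_DEFAULT_ASSAYS: list[tuple[str, str, str, int, bool]] = [
    # assay_id, rs_id, chromosome, position, y_linked
    ("C___1801627_10", "rs10869955", "9", 77_523_211, False),
    ("C___7421900_10", "rs1415762", "6", 125_081_641, False),
    ("C__27402849_10", "rs6927758", "6", 163_689_526, False),
    ("C__29619553_10", "rs9396715", "6", 10_022_280, False),
    ("C___1902433_10", "rs10771010", "12", 23_660_716, False),
    ("C___2728408_10", "rs560681", "1", 160_786_670, False),
    ("C___1250735_20", "rs1058083", "13", 100_038_233, False),
    ("C___1902433_20", "rs9546538", "13", 75_026_651, False),
    ("C___3227711_10", "rs7520386", "1", 14_155_402, False),
    ("C__30044763_10", "rs10776839", "9", 137_417_308, False),
    ("C__11821218_10", "rs9866013", "3", 57_335_645, False),
    ("C___1670459_10", "rs13182883", "5", 136_633_338, False),
    ("C__29619553_20", "rs13218440", "6", 12_059_954, False),
    ("C___8850710_10", "rs7704770", "5", 159_487_953, False),
    ("C___1007630_10", "rs430046", "16", 78_017_051, False),
    ("C__31386842_10", "rs9951171", "18", 9_749_879, False),
    ("C___7538087_10", "rs4530059", "14", 104_769_149, False),
    ("C__33211673_10", "rs7229946", "18", 21_413_869, False),
    ("C___2953330_10", "rs9905977", "17", 2_919_691, False),
    ("C__16205730_10", "rs2399332", "3", 109_325_586, False),
    ("C___8938211_20", "rs3780962", "10", 17_193_346, False),
    ("C___1122315_10", "rs4577050", "15", 53_616_322, False),
    ("C__11522992_10", "rs6444724", "3", 193_207_380, False),
    ("C___2301712_10", "rs2503107", "6", 152_697_706, False),
    ("C__26546714_10", "rs338882", "5", 178_690_725, False),
    ("C___3052001_10", "rs1410059", "10", 97_172_595, False),
    ("C___7452451_10", "rs2272998", "6", 148_761_456, False),
    ("C__11710740_10", "rs10092491", "8", 28_411_072, False),
    ("C___2255771_10", "rs1336071", "6", 94_537_440, False),
    # Y-linked assays last so that small toy panels stay autosomal.
    ("C___1027548_10", "", "Y", 2_655_180, True),
    ("C___8938211_10", "", "Y", 6_845_577, True),
    ("C___1083232_10", "", "Y", 14_850_341, True),
]

#: IDs of the three Y-chromosome assays, absent in all female samples.
DEFAULT_Y_ASSAYS: list[str] = [a[0] for a in _DEFAULT_ASSAYS if a[4]]


def default_panel(n_loci: int = 32) -> tuple[SNPAssay, ...]:
    """The first *n_loci* assays of the canonical 32-assay barcode panel."""
    if not 1 <= n_loci <= len(_DEFAULT_ASSAYS):
        raise ValueError(f"n_loci must be in [1, {len(_DEFAULT_ASSAYS)}]")
    return tuple(SNPAssay(*row) for row in _DEFAULT_ASSAYS[:n_loci])


# --- operations -------------------------------------------------------------


def infer_sex(profile: SNPProfile, y_assays: list[str]) -> Sex:
    """Infer sex from the Y-assay calls alone.

    FEMALE when all Y assays fail to amplify, MALE when all amplify with a
    determined genotype, INCONSISTENT otherwise (partial or undetermined Y
    amplification, e.g. a male/female chimera), UNKNOWN when the panel has
    no Y assays.
    """
    if not y_assays:
        return Sex.UNKNOWN
    cats = [profile.category(a) for a in y_assays]
    if all(c is Category.NOAMP for c in cats):
        return Sex.FEMALE
    if all(c in DETERMINED for c in cats):
        return Sex.MALE
    return Sex.INCONSISTENT


def profiles_match(a: SNPProfile, b: SNPProfile, assay_ids: list[str]) -> bool:
    """True when a and b agree at every locus where both are determined."""
    informative = [
        aid
        for aid in assay_ids
        if a.category(aid) in DETERMINED and b.category(aid) in DETERMINED
    ]
    return all(a.category(aid) == b.category(aid) for aid in informative)


def assign_references(
    profiles: list[SNPProfile],
    metadata: dict[str, ReferenceMeta] | None = None,
    assays: tuple[SNPAssay, ...] | None = None,
) -> ReferencePanel:
    """Build a reference registry from a batch of barcode profiles.

    ``reference_id`` is the profile's ``sample_id``.  Profiles from the same
    patient (identical at all informative loci) are allowed but raise a
    :class:`DuplicateProfileWarning`, mirroring diagnosis/relapse pairs.
    """
    if assays is None:
        n = len(profiles[0].calls) if profiles else 32
        assays = default_panel(n)
    panel = ReferencePanel(assays=assays)
    seen: dict[str, SNPProfile] = {}
    for prof in profiles:
        if prof.sample_id in seen:
            raise DuplicateReferenceError(
                f"reference_id {prof.sample_id!r} appears twice "
                f"(existing entry and new profile share the id)"
            )
        panel.check_profile(prof)
        seen[prof.sample_id] = prof
    for prof in profiles:
        for rid, other in panel.references.items():
            if profiles_match(prof, other, panel.assay_ids):
                warnings.warn(
                    f"{prof.sample_id!r} matches existing reference {rid!r} at all "
                    f"informative loci (same-patient duplicate?)",
                    DuplicateProfileWarning,
                    stacklevel=2,
                )
        panel.references[prof.sample_id] = prof
        meta = (metadata or {}).get(prof.sample_id)
        if meta is None:
            meta = ReferenceMeta(patient_id=prof.sample_id, sex=prof.inferred_sex)
        panel.metadata[prof.sample_id] = meta
    return panel


def add_calls(
    panel: ReferencePanel,
    new_profile: SNPProfile,
    meta: ReferenceMeta | None = None,
) -> ReferencePanel:
    """Return a new registry with *new_profile* appended; the input is unmodified."""
    if new_profile.sample_id in panel.references:
        raise DuplicateReferenceError(
            f"reference_id {new_profile.sample_id!r} already registered"
        )
    panel.check_profile(new_profile)
    for rid, other in panel.references.items():
        if profiles_match(new_profile, other, panel.assay_ids):
            warnings.warn(
                f"{new_profile.sample_id!r} matches existing reference {rid!r} at all "
                f"informative loci (same-patient duplicate?)",
                DuplicateProfileWarning,
                stacklevel=2,
            )
    if meta is None:
        meta = ReferenceMeta(patient_id=new_profile.sample_id, sex=new_profile.inferred_sex)
    return ReferencePanel(
        assays=panel.assays,
        references={**panel.references, new_profile.sample_id: new_profile},
        metadata={**panel.metadata, new_profile.sample_id: meta},
    )


# --- persistence ------------------------------------------------------------

_META_COLUMNS = ["reference_id", "patient_id", "sex", "provenance"]


def write_reference_csv(panel: ReferencePanel, path) -> None:
    """Write the registry as one row per reference: metadata then one column per assay."""
    rows = []
    for rid, prof in panel.references.items():
        meta = panel.metadata[rid]
        row = {
            "reference_id": rid,
            "patient_id": meta.patient_id,
            "sex": meta.sex.value,
            "provenance": meta.provenance,
        }
        row.update({aid: prof.category(aid).value for aid in panel.assay_ids})
        rows.append(row)
    df = pd.DataFrame(rows, columns=_META_COLUMNS + panel.assay_ids)
    df.to_csv(path, index=False)


def _assay_from_id(assay_id: str) -> SNPAssay:
    for row in _DEFAULT_ASSAYS:
        if row[0] == assay_id:
            return SNPAssay(*row)
    return SNPAssay(assay_id=assay_id)


def read_reference_csv(path, assays: tuple[SNPAssay, ...] | None = None) -> ReferencePanel:
    """Read a registry written by :func:`write_reference_csv`.

    When *assays* is omitted the panel is reconstructed from the header,
    resolving known default-panel assay IDs to their full annotation.
    """
    df = pd.read_csv(path, dtype=str)
    assay_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if assays is None:
        assays = tuple(_assay_from_id(c) for c in assay_cols)
    panel = ReferencePanel(assays=assays)
    for _, row in df.iterrows():
        rid = row["reference_id"]
        calls = {aid: GenotypeCall(Category(row[aid])) for aid in assay_cols}
        prof = SNPProfile(sample_id=rid, calls=calls)
        prof.inferred_sex = infer_sex(prof, panel.y_assay_ids) if panel.y_assay_ids else Sex.UNKNOWN
        if rid in panel.references:
            raise DuplicateReferenceError(f"reference_id {rid!r} duplicated in {path}")
        panel.check_profile(prof)
        panel.references[rid] = prof
        panel.metadata[rid] = ReferenceMeta(
            patient_id=row.get("patient_id", rid),
            sex=Sex(row["sex"]) if "sex" in row and pd.notna(row["sex"]) else Sex.UNKNOWN,
            provenance=row.get("provenance", "patient") if pd.notna(row.get("provenance", "patient")) else "patient",
        )
    return panel


def write_karyotype_csv(panel: ReferencePanel, path) -> None:
    rows = [
        {
            "reference_id": rid,
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "total_copies": r.total_copies,
            "allele2_copies": r.allele2_copies,
        }
        for rid, meta in panel.metadata.items()
        for r in meta.karyotype_regions
    ]
    pd.DataFrame(
        rows,
        columns=["reference_id", "chromosome", "start", "end", "total_copies", "allele2_copies"],
    ).to_csv(path, index=False)


def read_karyotype_csv(path) -> dict[str, tuple[KaryotypeRegion, ...]]:
    df = pd.read_csv(path, dtype={"chromosome": str})
    out: dict[str, list[KaryotypeRegion]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["reference_id"]), []).append(
            KaryotypeRegion(
                chromosome=str(row["chromosome"]),
                start=int(row["start"]),
                end=int(row["end"]),
                total_copies=int(row["total_copies"]),
                allele2_copies=int(row["allele2_copies"]),
            )
        )
    return {k: tuple(v) for k, v in out.items()}


def attach_karyotypes(
    panel: ReferencePanel, regions: dict[str, tuple[KaryotypeRegion, ...]]
) -> None:
    """Attach karyotype annotations to existing registry entries in place."""
    for rid, regs in regions.items():
        if rid not in panel.metadata:
            raise KeyError(f"karyotype annotation for unknown reference {rid!r}")
        panel.metadata[rid] = replace(panel.metadata[rid], karyotype_regions=regs)
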