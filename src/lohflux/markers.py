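"""Marker-strain genetics: maps, genotypes, phenotypes and LOH classification.

The assay strain is a diploid *S. cerevisiae* in which one homolog of
chromosome II ("IIa") carries four ectopic markers — ``TRP1`` near the left
telomere, a hygromycin-resistance cassette (``HYG``) centromere-proximal on
the left arm, ``URA3`` just right of the centromere, and a nourseothricin
cassette (``NAT``) near the right telomere — while the other homolog ("IIb")
is unmarked apart from a distinguishable (truncated, non-functional) ``TYR1``
allele that both homologs carry on the right arm.  Loss of the functional
``URA3`` allele is selected on 5-FOA; the retention pattern of the remaining
markers in a resistant colony identifies the class of the underlying
loss-of-heterozygosity (LOH) event:

=====================  ==============================================
growth pattern         LOH class
=====================  ==============================================
trp- hyg- nat-         chromosome loss (whole-homolog aneuploidy)
trp+ hyg+ nat+         local gene conversion at URA3
trp+ hyg+ nat-         segmental LOH of the right arm
trp+ hyg- nat-  /      complex event (one telomeric marker retained,
trp- hyg- nat+         everything else lost)
=====================  ==============================================

Any other 5-FOA-resistant pattern is outside the model and is surfaced as an
anomaly rather than silently binned.  Complex events are further resolved
with PCR zygosity calls at the retained telomeric locus and at the two-allele
``TYR1`` diagnostic locus.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Allele",
    "Locus",
    "MarkerMap",
    "DiploidGenotype",
    "ColonyPhenotype",
    "LOHClass",
    "ComplexSubclass",
    "Zygosity",
    "Call",
    "AnomalousPhenotypeError",
    "ConfigurationError",
    "InvalidStateError",
    "HOMOLOG_A",
    "HOMOLOG_B",
    "default_marker_map",
    "telomeric_ura3_map",
    "starting_genotype",
    "phenotype_of",
    "classify_phenotype",
    "subclassify_complex",
    "apply_event",
]

HOMOLOG_A = "IIa"  # the marked homolog
HOMOLOG_B = "IIb"


class ConfigurationError(ValueError):
    """A genotype/map inconsistency or an invalid marker map."""


class InvalidStateError(ValueError):
    """An event applied to a genotype it cannot act on."""


class AnomalousPhenotypeError(ValueError):
    """A 5-FOA-resistant growth pattern outside the four modelled classes.

    Carries the offending pattern so callers can tally anomalies instead of
    discarding them.
    """

    def __init__(self, pattern: str):
        self.pattern = pattern
        super().__init__(f"anomalous 5FOA-resistant marker pattern: {pattern}")


class Call(enum.Enum):
    """Ternary growth call on a test medium."""

    YES = "+"
    NO = "-"
    UNTESTED = "NA"

    @classmethod
    def parse(cls, token: str) -> "Call":
        token = str(token).strip()
        aliases = {
            "+": cls.YES, "yes": cls.YES, "1": cls.YES, "true": cls.YES,
            "-": cls.NO, "−": cls.NO, "no": cls.NO, "0": cls.NO,
            "false": cls.NO,
            "na": cls.UNTESTED, "nan": cls.UNTESTED, "": cls.UNTESTED,
        }
        try:
            return aliases[token.lower()]
        except KeyError:
            raise ValueError(f"cannot parse growth call {token!r}") from None


class Zygosity(enum.Enum):
    HETEROZYGOUS = "het"
    HOMOZYGOUS = "hom"
    UNTESTED = "NA"

    @classmethod
    def parse(cls, token: str) -> "Zygosity":
        token = str(token).strip().lower()
        aliases = {
            "het": cls.HETEROZYGOUS, "heterozygous": cls.HETEROZYGOUS,
            "hom": cls.HOMOZYGOUS, "homozygous": cls.HOMOZYGOUS,
            "na": cls.UNTESTED, "nan": cls.UNTESTED, "": cls.UNTESTED,
        }
        try:
            return aliases[token]
        except KeyError:
            raise ValueError(f"cannot parse zygosity call {token!r}") from None


class LOHClass(enum.Enum):
    """The four modelled LOH scenarios plus the unselected state."""

    CHROMOSOME_LOSS = "CL"
    GENE_CONVERSION = "GC"
    SEGMENTAL = "SEGMENTAL"
    COMPLEX = "COMPLEX"
    NO_LOH = "NO_LOH"


class ComplexSubclass(enum.Enum):
    """Resolution of a complex event from zygosity genotyping.

    ``HET_TELOMERIC``: the retained telomeric marker locus is heterozygous —
    consistent with break-induced replication through the centromere or with
    ectopic capture of the telomeric fragment (the whole marked homolog is
    lost but its telomeric segment survives alongside the intact homolog).

    ``HALF_CO_NAT_TYR1`` / ``HALF_CO_TYR1_URA3``: the retained locus is
    homozygous for the marked-homolog allele, and the TYR1 diagnostic allele
    places the half-crossover breakpoint between NAT and TYR1, or between
    TYR1 and URA3, respectively.

    ``ANOMALOUS``: retained locus heterozygous while TYR1 is homozygous —
    a configuration no modelled mechanism produces.
    """

    HALF_CO_NAT_TYR1 = "HALF_CO_NAT_TYR1"
    HALF_CO_TYR1_URA3 = "HALF_CO_TYR1_URA3"
    HET_TELOMERIC = "HET_TELOMERIC"
    UNRESOLVED = "UNRESOLVED"
    ANOMALOUS = "ANOMALOUS"


@dataclass(frozen=True)
class Allele:
    """One allele at a locus: a PCR-distinguishable label plus functionality."""

    label: str
    functional: bool


@dataclass(frozen=True)
class Locus:
    """A marker locus with its position and the allele carried by each homolog.

    ``channel`` names the growth phenotype the locus reports on
    (``trp``/``hyg``/``nat`` for dominant drug/prototrophy markers, ``ura``
    for the counter-selected URA3, ``None`` for diagnostic-only loci such as
    TYR1).
    """

    name: str
    kb: float
    channel: Optional[str]
    allele_a: Allele
    allele_b: Allele
    dominant: bool = True


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker loci on the chromosome II homolog pair.

    Positions are 1-based kilobase coordinates in the standard left-to-right
    orientation of chromosome II.
    """

    loci: tuple[Locus, ...]
    length_kb: float
    centromere_kb: float
    name: str = "custom"

    def __post_init__(self) -> None:
        positions = [locus.kb for locus in self.loci]
        if sorted(positions) != positions or len(set(positions)) != len(positions):
            raise ConfigurationError("locus positions must be strictly increasing")
        if positions and not (positions[0] <= self.centromere_kb <= positions[-1]):
            raise ConfigurationError(
                "centromere must lie between the leftmost and rightmost locus"
            )
        if positions and positions[-1] > self.length_kb:
            raise ConfigurationError("locus position beyond chromosome end")

    def locus(self, name: str) -> Locus:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise ConfigurationError(f"locus {name!r} not in marker map")

    def locus_names(self) -> tuple[str, ...]:
        return tuple(locus.name for locus in self.loci)

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[Mapping],
        length_kb: float,
        centromere_kb: float,
        name: str = "custom",
    ) -> "MarkerMap":
        """Build a map from per-homolog JSON entries.

        Each entry is ``{name, homolog, kb, dominant, allele, functional,
        channel}``; loci named on only one homolog get an implicit
        non-functional null allele on the other.
        """
        grouped: dict[str, dict] = {}
        for entry in entries:
            slot = grouped.setdefault(
                entry["name"],
                {"kb": entry["kb"], "channel": entry.get("channel"),
                 "dominant": entry.get("dominant", True), "alleles": {}},
            )
            allele = Allele(
                label=entry.get("allele", f"{entry['name']}-?"),
                functional=bool(entry.get("functional", True)),
            )
            slot["alleles"][entry["homolog"]] = allele
            if entry.get("channel"):
                slot["channel"] = entry["channel"]
        loci = []
        for locus_name, slot in grouped.items():
            allele_a = slot["alleles"].get(
                HOMOLOG_A, Allele(f"{locus_name}-1", False)
            )
            allele_b = slot["alleles"].get(
                HOMOLOG_B, Allele(f"{locus_name}-1", False)
            )
            loci.append(
                Locus(locus_name, slot["kb"], slot["channel"],
                      allele_a, allele_b, slot["dominant"])
            )
        loci.sort(key=lambda locus: locus.kb)
        return cls(tuple(loci), length_kb, centromere_kb, name)

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerMap":
        payload = json.loads(Path(path).read_text())
        return cls.from_entries(
            payload["loci"],
            length_kb=payload["length_kb"],
            centromere_kb=payload["centromere_kb"],
            name=payload.get("name", "custom"),
        )


# Chromosome II is ~813 kb with its centromere at ~238 kb. URA3 sits at
# position 241 kb next to the centromere; NAT at 795 kb near the right
# telomere; the TYR1 truncation alleles ~230 kb from the right telomere.
_CHR2_LENGTH_KB = 813.0
_CHR2_CEN_KB = 238.0


def default_marker_map() -> MarkerMap:
    """The centromeric-URA3 assay strain (the main configuration)."""
    return MarkerMap(
        loci=(
            Locus("TRP1", 10.0, "trp", Allele("TRP1-2", True), Allele("TRP1-1", False)),
            Locus("HYG", 230.0, "hyg", Allele("HYG-2", True), Allele("HYG-1", False)),
            Locus("URA3", 241.0, "ura", Allele("URA3-2", True), Allele("URA3-1", False)),
            Locus("TYR1", 583.0, None, Allele("TYR1-2", False), Allele("TYR1-1", False)),
            Locus("NAT", 795.0, "nat", Allele("NAT-2", True), Allele("NAT-1", False)),
        ),
        length_kb=_CHR2_LENGTH_KB,
        centromere_kb=_CHR2_CEN_KB,
        name="cen-URA3",
    )


def telomeric_ura3_map() -> MarkerMap:
    """Variant strain with URA3 inserted next to NAT on the right arm."""
    return MarkerMap(
        loci=(
            Locus("TRP1", 10.0, "trp", Allele("TRP1-2", True), Allele("TRP1-1", False)),
            Locus("HYG", 230.0, "hyg", Allele("HYG-2", True), Allele("HYG-1", False)),
            Locus("TYR1", 583.0, None, Allele("TYR1-2", False), Allele("TYR1-1", False)),
            Locus("URA3", 793.0, "ura", Allele("URA3-2", True), Allele("URA3-1", False)),
            Locus("NAT", 795.0, "nat", Allele("NAT-2", True), Allele("NAT-1", False)),
        ),
        length_kb=_CHR2_LENGTH_KB,
        centromere_kb=_CHR2_CEN_KB,
        name="tel-URA3",
    )


def get_marker_map(selector: str) -> MarkerMap:
    """Resolve ``cen``/``tel`` keywords or a JSON path to a MarkerMap."""
    if selector in ("cen", "cen-URA3", "default"):
        return default_marker_map()
    if selector in ("tel", "tel-URA3", "telomeric"):
        return telomeric_ura3_map()
    return MarkerMap.from_json(selector)


@dataclass(frozen=True)
class DiploidGenotype:
    """Per-homolog allele states plus homolog copy number.

    ``alleles[homolog][locus]`` is the allele carried there; a homolog with
    copy number 0 contributes no alleles regardless of its stored states.
    ``fragment`` models a surviving acentric telomeric segment (BIR copy or
    ectopically captured piece) as extra allele content.
    """

    alleles: Mapping[str, Mapping[str, Allele]]
    copy_number: Mapping[str, int] = field(
        default_factory=lambda: {HOMOLOG_A: 1, HOMOLOG_B: 1}
    )
    fragment: Mapping[str, Allele] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for homolog, copies in self.copy_number.items():
            if copies not in (0, 1):
                raise ConfigurationError(
                    f"homolog {homolog} copy number must be 0 or 1, got {copies}"
                )

    def alleles_at(self, locus_name: str) -> tuple[Allele, ...]:
        """All alleles present at a locus on retained material."""
        present = []
        for homolog, locus_alleles in self.alleles.items():
            if self.copy_number.get(homolog, 0) >= 1 and locus_name in locus_alleles:
                present.append(locus_alleles[locus_name])
        if locus_name in self.fragment:
            present.append(self.fragment[locus_name])
        return tuple(present)

    def zygosity_at(self, locus_name: str) -> tuple[Zygosity, frozenset[str]]:
        """(zygosity, allele labels) as a PCR genotyping assay would read them."""
        labels = frozenset(a.label for a in self.alleles_at(locus_name))
        if len(labels) >= 2:
            return Zygosity.HETEROZYGOUS, labels
        return Zygosity.HOMOZYGOUS, labels


def starting_genotype(marker_map: MarkerMap) -> DiploidGenotype:
    """The unselected heterozygous diploid the assay begins from."""
    return DiploidGenotype(
        alleles={
            HOMOLOG_A: {locus.name: locus.allele_a for locus in marker_map.loci},
            HOMOLOG_B: {locus.name: locus.allele_b for locus in marker_map.loci},
        }
    )


@dataclass(frozen=True)
class ColonyPhenotype:
    """Growth calls on the four test media plus optional zygosity calls."""

    foa_resistant: Call
    nat_resistant: Call
    hyg_resistant: Call
    trp_prototroph: Call
    nat_zygosity: Zygosity = Zygosity.UNTESTED
    trp1_zygosity: Zygosity = Zygosity.UNTESTED
    tyr1_alleles: Optional[str] = None  # "1", "2", "both" or None

    def growth_pattern(self) -> str:
        def sym(call: Call, label: str) -> str:
            return {Call.YES: f"{label}+", Call.NO: f"{label}-",
                    Call.UNTESTED: f"{label}?"}[call]

        return " ".join(
            [sym(self.foa_resistant, "foa"), sym(self.trp_prototroph, "trp"),
             sym(self.hyg_resistant, "hyg"), sym(self.nat_resistant, "nat")]
        )


def phenotype_of(genotype: DiploidGenotype, marker_map: MarkerMap) -> ColonyPhenotype:
    """Predict the colony phenotype of a genotype under the marker map.

    Dominant markers (drug resistances, TRP1 prototrophy) score positive iff
    at least one functional allele is present on retained material; 5-FOA
    resistance is recessive — positive iff *no* functional URA3 allele
    remains anywhere.
    """
    map_names = set(marker_map.locus_names())
    for homolog_alleles in genotype.alleles.values():
        unknown = set(homolog_alleles) - map_names
        if unknown:
            raise ConfigurationError(
                f"genotype carries loci absent from marker map: {sorted(unknown)}"
            )
    unknown = set(genotype.fragment) - map_names
    if unknown:
        raise ConfigurationError(
            f"fragment carries loci absent from marker map: {sorted(unknown)}"
        )

    def functional_present(locus_name: str) -> bool:
        return any(a.functional for a in genotype.alleles_at(locus_name))

    calls = {"trp": Call.NO, "hyg": Call.NO, "nat": Call.NO}
    ura_functional = False
    for locus in marker_map.loci:
        if locus.channel == "ura":
            ura_functional = ura_functional or functional_present(locus.name)
        elif locus.channel in calls and functional_present(locus.name):
            calls[locus.channel] = Call.YES

    nat_zyg, _ = genotype.zygosity_at("NAT") if "NAT" in map_names else (Zygosity.UNTESTED, frozenset())
    trp_zyg, _ = genotype.zygosity_at("TRP1") if "TRP1" in map_names else (Zygosity.UNTESTED, frozenset())
    tyr1: Optional[str] = None
    if "TYR1" in map_names:
        _, labels = genotype.zygosity_at("TYR1")
        detected = {label.rsplit("-", 1)[-1] for label in labels}
        if detected == {"1", "2"}:
            tyr1 = "both"
        elif detected:
            tyr1 = detected.pop()

    return ColonyPhenotype(
        foa_resistant=Call.NO if ura_functional else Call.YES,
        nat_resistant=calls["nat"],
        hyg_resistant=calls["hyg"],
        trp_prototroph=calls["trp"],
        nat_zygosity=nat_zyg,
        trp1_zygosity=trp_zyg,
        tyr1_alleles=tyr1,
    )


_CLASS_TABLE: dict[tuple[Call, Call, Call], LOHClass] = {
    # key = (trp, hyg, nat) for a 5FOA-resistant colony
    (Call.NO, Call.NO, Call.NO): LOHClass.CHROMOSOME_LOSS,
    (Call.YES, Call.YES, Call.YES): LOHClass.GENE_CONVERSION,
    (Call.YES, Call.YES, Call.NO): LOHClass.SEGMENTAL,
    (Call.YES, Call.NO, Call.NO): LOHClass.COMPLEX,
    (Call.NO, Call.NO, Call.YES): LOHClass.COMPLEX,
}


def classify_phenotype(pheno: ColonyPhenotype) -> LOHClass:
    """Assign a 5-FOA-resistant colony to an LOH class from its growth calls.

    Raises :class:`AnomalousPhenotypeError` for resistant patterns outside
    the four modelled scenarios (e.g. hygromycin resistance retained without
    TRP1) so that callers report them rather than bin them.
    """
    growth = (pheno.foa_resistant, pheno.trp_prototroph,
              pheno.hyg_resistant, pheno.nat_resistant)
    if any(call is Call.UNTESTED for call in growth):
        raise ValueError(
            "classification requires definite yes/no calls on all four media"
        )
    if pheno.foa_resistant is Call.NO:
        return LOHClass.NO_LOH
    key = (pheno.trp_prototroph, pheno.hyg_resistant, pheno.nat_resistant)
    try:
        return _CLASS_TABLE[key]
    except KeyError:
        raise AnomalousPhenotypeError(pheno.growth_pattern()) from None


def subclassify_complex(pheno: ColonyPhenotype) -> ComplexSubclass:
    """Resolve a complex event from zygosity genotyping.

    The retained telomeric side is read from the growth calls (NAT+ vs
    TRP+). On the NAT side the TYR1 diagnostic locus localises half-crossover
    breakpoints; on the TRP side only the heterozygous-vs-homozygous state of
    TRP1 is informative, so homozygous TRP-side events stay unresolved.
    Missing zygosity data yields ``UNRESOLVED``, never an error.
    """
    if classify_phenotype(pheno) is not LOHClass.COMPLEX:
        raise ValueError("subclassification applies only to COMPLEX colonies")

    nat_side = pheno.nat_resistant is Call.YES
    retained_zyg = pheno.nat_zygosity if nat_side else pheno.trp1_zygosity
    if retained_zyg is Zygosity.UNTESTED:
        return ComplexSubclass.UNRESOLVED

    if not nat_side:
        if retained_zyg is Zygosity.HETEROZYGOUS:
            return ComplexSubclass.HET_TELOMERIC
        return ComplexSubclass.UNRESOLVED  # breakpoint not localisable on left arm

    tyr1 = pheno.tyr1_alleles
    if retained_zyg is Zygosity.HETEROZYGOUS:
        if tyr1 in ("1", "2"):
            return ComplexSubclass.ANOMALOUS  # never observed experimentally
        return ComplexSubclass.HET_TELOMERIC
    # retained NAT locus homozygous for the marked allele
    if tyr1 == "1":
        return ComplexSubclass.HALF_CO_NAT_TYR1
    if tyr1 == "2":
        return ComplexSubclass.HALF_CO_TYR1_URA3
    if tyr1 == "both":
        return ComplexSubclass.ANOMALOUS
    return ComplexSubclass.UNRESOLVED


def _require_intact_start(genotype: DiploidGenotype, marker_map: MarkerMap) -> None:
    if genotype.copy_number.get(HOMOLOG_A, 0) < 1:
        raise InvalidStateError("event requires the marked homolog IIa to be present")
    ura_alleles = genotype.alleles_at("URA3")
    functional = [a for a in ura_alleles if a.functional]
    if len(ura_alleles) < 2 or len(functional) != 1:
        raise InvalidStateError("event model starts from a URA3-heterozygous diploid")


def _replace_segment(
    genotype: DiploidGenotype, marker_map: MarkerMap, from_kb: float
) -> dict[str, Allele]:
    """IIa alleles for loci at or right of ``from_kb`` copied onto IIb."""
    new_b = dict(genotype.alleles[HOMOLOG_B])
    for locus in marker_map.loci:
        if locus.kb >= from_kb:
            new_b[locus.name] = genotype.alleles[HOMOLOG_A][locus.name]
    return new_b


def apply_event(
    genotype: DiploidGenotype,
    event: LOHClass | ComplexSubclass,
    marker_map: MarkerMap,
) -> DiploidGenotype:
    """Apply an LOH event to the starting heterozygous genotype.

    Event semantics (all leave homolog IIb intact unless stated):

    * ``CHROMOSOME_LOSS`` — homolog IIa is lost entirely.
    * ``GENE_CONVERSION`` — the functional URA3 allele on IIa is replaced by
      the IIb allele; nothing else changes.
    * ``SEGMENTAL`` — IIa is homozygosed from URA3 through the right
      telomere (crossover/BIR-type tract).
    * ``COMPLEX`` — realised as the NAT-side ``HET_TELOMERIC`` scenario.
    * ``HET_TELOMERIC`` — IIa is lost but its telomeric fragment (distal to
      URA3, carrying TYR1-2 and NAT-2) survives via BIR/ectopic capture.
    * ``HALF_CO_NAT_TYR1`` / ``HALF_CO_TYR1_URA3`` — half-crossover: the IIa
      segment distal to the breakpoint replaces the IIb segment; the rest of
      IIa is lost.
    * ``NO_LOH`` — identity.
    """
    if event is LOHClass.NO_LOH:
        return genotype
    _require_intact_start(genotype, marker_map)

    if event is LOHClass.CHROMOSOME_LOSS:
        return replace(genotype, copy_number={HOMOLOG_A: 0, HOMOLOG_B: 1})

    if event is LOHClass.GENE_CONVERSION:
        new_a = dict(genotype.alleles[HOMOLOG_A])
        new_a["URA3"] = genotype.alleles[HOMOLOG_B]["URA3"]
        return replace(
            genotype, alleles={HOMOLOG_A: new_a, HOMOLOG_B: dict(genotype.alleles[HOMOLOG_B])}
        )

    ura_kb = marker_map.locus("URA3").kb
    tyr_kb = marker_map.locus("TYR1").kb if "TYR1" in marker_map.locus_names() else None
    nat_kb = marker_map.locus("NAT").kb

    if event is LOHClass.SEGMENTAL:
        new_a = dict(genotype.alleles[HOMOLOG_A])
        for locus in marker_map.loci:
            if locus.kb >= ura_kb:
                new_a[locus.name] = genotype.alleles[HOMOLOG_B][locus.name]
        return replace(
            genotype, alleles={HOMOLOG_A: new_a, HOMOLOG_B: dict(genotype.alleles[HOMOLOG_B])}
        )

    if event is LOHClass.COMPLEX:
        event = ComplexSubclass.HET_TELOMERIC

    if event is ComplexSubclass.HET_TELOMERIC:
        # fragment retains everything distal to URA3 on the right arm
        cut_kb = ura_kb + 1e-9
        fragment = {
            locus.name: genotype.alleles[HOMOLOG_A][locus.name]
            for locus in marker_map.loci
            if locus.kb > cut_kb
        }
        return replace(
            genotype, copy_number={HOMOLOG_A: 0, HOMOLOG_B: 1}, fragment=fragment
        )

    if event is ComplexSubclass.HALF_CO_NAT_TYR1:
        if tyr_kb is None:
            raise ConfigurationError("map lacks the TYR1 diagnostic locus")
        breakpoint_kb = (tyr_kb + nat_kb) / 2.0
    elif event is ComplexSubclass.HALF_CO_TYR1_URA3:
        if tyr_kb is None:
            raise ConfigurationError("map lacks the TYR1 diagnostic locus")
        breakpoint_kb = (ura_kb + tyr_kb) / 2.0
    else:
        raise ValueError(f"cannot apply event {event!r}")

    new_b = _replace_segment(genotype, marker_map, breakpoint_kb)
    return replace(
        genotype,
        alleles={HOMOLOG_A: dict(genotype.alleles[HOMOLOG_A]), HOMOLOG_B: new_b},
        copy_number={HOMOLOG_A: 0, HOMOLOG_B: 1},
    )
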