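"""Qualifying-variant classification.

Coding variants are sorted into four mutually exclusive classes used for
burden testing, plus OTHER for everything that satisfies no rule:

* ``PTV`` — protein-truncating: frameshift, splice acceptor/donor,
  stop-gained or start-lost consequences.
* ``D_MIS`` — damaging missense: PolyPhen-2 "probably damaging" AND SIFT
  "deleterious" AND CADD (PHRED) > 20.
* ``B_MIS`` — benign missense: concordant benign calls from PolyPhen-2 and
  SIFT, or CADD < 15, on a missense-family consequence.
* ``SYNONYMOUS`` — synonymous_variant; the burden-test negative control.

A variant is *qualifying* for burden analysis when its class matches the
model and its minor-allele frequency is below the rarity threshold (0.5%
by default) both in the cohort and in every reference panel supplied
(gnomAD, 1000 Genomes, ESP, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class VariantClass(str, Enum):
    PTV = "PTV"
    D_MIS = "D_MIS"
    B_MIS = "B_MIS"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


PTV_CONSEQUENCES = frozenset(
    {
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "start_lost",
    }
)

# missense family per the annotation scheme (inframe indels and stop_lost
# are handled with missense by the deleteriousness predictors)
MISSENSE_CONSEQUENCES = frozenset(
    {"missense_variant", "inframe_deletion", "inframe_insertion", "stop_lost"}
)

SYNONYMOUS_CONSEQUENCES = frozenset({"synonymous_variant"})


@dataclass
class VariantAnnotation:
    """Per-variant annotation record (VCF coordinates, 1-based).

    ``variant_id`` is normalized to ``chrom-pos-ref-alt``
    (e.g. ``chr22-38875700-CT-C``). Missing categorical predictors are
    ``None``; ``ref_afs`` maps reference-panel name to allele frequency.
    """

    variant_id: str
    consequence: str
    gene: Optional[str] = None
    polyphen: Optional[str] = None
    sift: Optional[str] = None
    cadd_phred: Optional[float] = None
    loftee: Optional[str] = None
    ref_afs: Mapping[str, float] = field(default_factory=dict)
    low_complexity: bool = False
    vqsr_pass: bool = True

    def __post_init__(self):
        if not self.consequence:
            raise ValueError(f"variant {self.variant_id}: consequence is empty")
        for panel, af in self.ref_afs.items():
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(
                    f"variant {self.variant_id}: {panel} AF {af} outside [0,1]"
                )


def classify_consequence(ann: VariantAnnotation) -> VariantClass:
    """Assign exactly one of the five class labels to an annotated variant.

    Damaging missense requires all three of probably_damaging (PolyPhen-2),
    deleterious (SIFT) and CADD > 20; a missing predictor can therefore
    never produce D_MIS. Benign missense is reachable through either the
    concordant benign predictions or CADD < 15 alone.
    """
    csq = ann.consequence
    if not csq:
        raise ValueError("missing consequence")
    if csq in PTV_CONSEQUENCES:
        return VariantClass.PTV
    if csq in SYNONYMOUS_CONSEQUENCES:
        return VariantClass.SYNONYMOUS
    if csq in MISSENSE_CONSEQUENCES:
        if (
            ann.polyphen == "probably_damaging"
            and ann.sift == "deleterious"
            and ann.cadd_phred is not None
            and ann.cadd_phred > 20
        ):
            return VariantClass.D_MIS
        benign_calls = {ann.polyphen, ann.sift}
        concordant_benign = (
            ann.polyphen is not None
            and ann.sift is not None
            and "benign" in benign_calls
            and "tolerated" in benign_calls
        )
        if concordant_benign or (ann.cadd_phred is not None and ann.cadd_phred < 15):
            return VariantClass.B_MIS
        return VariantClass.OTHER
    return VariantClass.OTHER


def is_rare(
    ann: VariantAnnotation, cohort_af: float, threshold: float = 0.005
) -> bool:
    """True iff the folded MAF is below ``threshold`` in the cohort and in
    every reference panel carried by the annotation (a panel with no
    frequency recorded counts as 0)."""
    if threshold < 0:
        raise ValueError(f"negative MAF threshold {threshold}")
    if not (0.0 <= cohort_af <= 1.0):
        raise ValueError(f"cohort AF {cohort_af} outside [0,1]")
    if min(cohort_af, 1.0 - cohort_af) >= threshold:
        return False
    for af in ann.ref_afs.values():
        if af is None:
            continue
        if min(af, 1.0 - af) >= threshold:
            return False
    return True
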