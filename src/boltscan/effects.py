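"""Coding-sequence variant consequence calling.

Applies SNPs and short indels to a CDS, translates reference and edited
sequences with the standard nuclear genetic code, and classifies the
consequence (synonymous, missense, in-frame indel, stop gained/lost,
frameshift) with a severity-ordered primary kind. Truncating variants are
described as "<alt> instead of <ref> aa" — the convention used to flag a
frameshifting 2-bp deletion that shortens a 633-aa protein to 203 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

_ACGT = set("ACGT")

# most severe first
SEVERITY = ("frameshift", "stop_gained", "stop_lost", "inframe_indel", "missense", "synonymous", "no_change")


class VariantApplicationError(ValueError):
    """Reference mismatch or overlapping variants."""


@dataclass(frozen=True)
class CodingSequence:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq != self.sequence:
            object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError(f"CDS {self.id}: length must be >= 3")
        bad = set(seq) - _ACGT
        if bad:
            raise ValueError(f"CDS {self.id}: non-ACGT characters {sorted(bad)}")


@dataclass(frozen=True)
class CdsVariant:
    """An edit at a 1-based CDS position; ``ref`` empty = insertion before
    ``pos``, ``alt`` empty = deletion of ``ref``."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")

    @property
    def net_length(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class Consequence:
    kind: str
    ref_protein_length: int
    alt_protein_length: int
    description: str
    flags: tuple[str, ...] = ()


def apply_variants(cds: CodingSequence, variants: Sequence[CdsVariant]) -> CodingSequence:
    """Edit the CDS, applying variants right-to-left so earlier coordinates
    stay valid. Variants must not overlap and each ``ref`` must match."""
    spans = []
    for v in variants:
        end = v.pos + max(len(v.ref), 1) - 1 if v.ref else v.pos - 1
        spans.append((v.pos, end, v))
    spans.sort(key=lambda t: t[0])
    for (s1, e1, _), (s2, _, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise VariantApplicationError(f"overlapping variants at positions {s1} and {s2}")
    seq = cds.sequence
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - 1
        if v.ref:
            if seq[i : i + len(v.ref)] != v.ref:
                raise VariantApplicationError(
                    f"reference mismatch at CDS position {v.pos}: "
                    f"expected {v.ref!r}, found {seq[i : i + len(v.ref)]!r}"
                )
            seq = seq[:i] + v.alt + seq[i + len(v.ref) :]
        else:
            seq = seq[:i] + v.alt + seq[i:]
    return CodingSequence(cds.id, seq)


def translate(cds: CodingSequence) -> tuple[str, bool]:
    """Translate from position 1 with the standard code, stopping at the
    first stop codon (excluded). Returns (protein, stop_found); a trailing
    incomplete codon is ignored."""
    n = len(cds.sequence) - len(cds.sequence) % 3
    full = str(Seq(cds.sequence[:n]).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], True


def call_consequence(
    ref_cds: CodingSequence, variants: Sequence[CdsVariant]
) -> Consequence:
    """Classify the joint consequence of ``variants`` on ``ref_cds``.

    Primary kind is the most severe applicable: frameshift > stop_gained >
    stop_lost > inframe_indel > missense > synonymous > no_change. Any
    protein truncation is described as "<alt> instead of <ref> aa".
    """
    alt_cds = apply_variants(ref_cds, variants)
    ref_protein, ref_has_stop = translate(ref_cds)
    alt_protein, alt_has_stop = translate(alt_cds)
    net = sum(v.net_length for v in variants)
    frameshift = net % 3 != 0
    assert frameshift == (sum(len(v.alt) - len(v.ref) for v in variants) % 3 != 0)

    flags: list[str] = []
    if frameshift:
        flags.append("frameshift")
        if len(alt_protein) < len(ref_protein):
            flags.append("stop_gained")
    else:
        # an in-frame indel of net/3 codons shifts the expected protein
        # length by that amount; deviations beyond it mean a stop moved
        delta = net // 3
        if len(alt_protein) < len(ref_protein) + delta:
            flags.append("stop_gained")
        if len(alt_protein) > len(ref_protein) + delta or (ref_has_stop and not alt_has_stop):
            flags.append("stop_lost")
        if net != 0:
            flags.append("inframe_indel")
        elif len(alt_protein) == len(ref_protein) and alt_protein != ref_protein:
            flags.append("missense")
        if alt_protein == ref_protein:
            flags.append("no_change" if alt_cds.sequence == ref_cds.sequence else "synonymous")
    if not ref_has_stop or not alt_has_stop:
        flags.append("no_stop_codon")

    kind = next(k for k in SEVERITY if k in flags)
    if len(alt_protein) < len(ref_protein):
        description = f"{len(alt_protein)} instead of {len(ref_protein)} aa"
    elif alt_protein == ref_protein:
        description = "protein unchanged"
    else:
        description = f"{len(alt_protein)} aa ({kind})"
    return Consequence(
        kind=kind,
        ref_protein_length=len(ref_protein),
        alt_protein_length=len(alt_protein),
        description=description,
        flags=tuple(f for f in flags if f in SEVERITY or f == "no_stop_codon"),
    )


def make_truncation_example(
    ref_len_aa: int = 633, alt_len_aa: int = 203, deletion_codon: int = 191
) -> tuple[CodingSequence, CdsVariant]:
    """Engineer a synthetic CDS where a 2-bp deletion in ``deletion_codon``
    frameshifts into a premature stop, truncating a ``ref_len_aa``-aa
    protein to ``alt_len_aa`` aa (defaults mirror a 633 -> 203 aa case).

    Construction: ATG + GAA repeats + terminal TAA, with codon
    ``alt_len_aa + 1`` = GAT and the next = AAG so the -2 shifted frame
    reads TAA exactly at edited codon ``alt_len_aa + 1``, while the
    reference frame stays stop-free until its terminal codon.
    """
    if not 1 < deletion_codon < alt_len_aa:
        raise ValueError("deletion_codon must lie strictly between 1 and alt_len_aa")
    if alt_len_aa + 2 > ref_len_aa:
        raise ValueError("alt_len_aa must be at most ref_len_aa - 2")
    codons = ["ATG"] + ["GAA"] * (ref_len_aa - 1) + ["TAA"]
    codons[alt_len_aa] = "GAT"  # codon alt_len_aa + 1
    codons[alt_len_aa + 1] = "AAG"
    cds = CodingSequence("synthetic_truncation_demo", "".join(codons))
    # delete the 2nd and 3rd base of the deletion codon (both "A" in GAA)
    variant = CdsVariant(pos=3 * deletion_codon - 1, ref="AA", alt="")
    return cds, variant
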