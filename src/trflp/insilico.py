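"""In-silico amplification and terminal restriction fragment (T-RF) prediction.

This module predicts the fragment a capillary sequencer would size in a
T-RFLP experiment: a degenerate primer pair is matched against a template,
the amplicon is extracted and oriented so the fluorescently labeled primer's
5' end sits at position 0, and the first restriction site downstream of the
label defines the T-RF length.

Coordinates are 0-based half-open internally; the CSV export reports T-RF
lengths in bp as capillary electrophoresis would (label to first cut,
primer bases included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

# IUPAC nucleotide codes -> set of unambiguous bases
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerSiteError(ValueError):
    """Raised when amplification fails: zero or multiple sites for a primer."""

    def __init__(self, primer_name: str, n_sites: int):
        self.primer_name = primer_name
        self.n_sites = n_sites
        what = "no site" if n_sites == 0 else f"{n_sites} sites"
        super().__init__(f"primer {primer_name!r}: {what} on template (need exactly 1)")


@dataclass(frozen=True)
class DegeneratePrimer:
    """A PCR primer written in IUPAC code, 5'->3'.

    ``role`` is "forward" or "reverse"; ``labeled`` marks the 5' fluorophore.
    In the mcrA workflow the reverse primer carries the label, so amplicons
    are reported on the reverse-complement strand.
    """

    name: str
    sequence: str
    role: str = "forward"
    labeled: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in primer {self.name!r}: {sorted(bad)}")
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be 'forward' or 'reverse', got {self.role!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease defined by recognition site and cut offset.

    ``cut_offset`` is counted in bases from the 5' end of the recognition
    site on the scanned strand: HaeIII GG^CC has offset 2, MspI C^CGG
    offset 1.
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool = True

    def __post_init__(self):
        rec = self.recognition.upper()
        if set(rec) - set("ACGT"):
            raise ValueError("recognition site must be unambiguous ACGT")
        if not (0 <= self.cut_offset <= len(rec)):
            raise ValueError("cut_offset out of range")
        if self.palindromic and reverse_complement(rec) != rec:
            raise ValueError(f"{self.name}: recognition {rec} is not palindromic; "
                             "flag palindromic=False explicitly")
        object.__setattr__(self, "recognition", rec)


# Standard REBASE definitions for the two enzymes of the dual-digest workflow.
HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
MSPI = RestrictionEnzyme("MspI", "CCGG", 1)

# The mcrA primer pair (mlas / mcrA-rev); the reverse primer is 5'-labeled
# for fragment sizing.
MLAS = DegeneratePrimer("mlas", "GGTGGTGTMGGDTTCACMCARTA", role="forward")
MCRA_REV = DegeneratePrimer("mcrA-rev", "CGTTCATBGCGTAGTTVGGRTAGT", role="reverse",
                            labeled=True)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product oriented 5'->3' on the labeled strand."""

    sequence: str
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TRFPrediction:
    """Length of the labeled terminal fragment after digestion.

    When the amplicon carries no recognition site, ``cut_found`` is False and
    ``length_bp`` is the full amplicon length; downstream code decides what
    to do with uncut amplicons.
    """

    enzyme_name: str
    length_bp: int
    cut_found: bool


@dataclass
class ReferenceTaxon:
    """A phylotype with its predicted T-RF length under each enzyme."""

    taxon_label: str
    sequence_id: str
    trf_by_enzyme: dict[str, int] = field(default_factory=dict)


def _iupac_match(pattern: str, window: str, max_mismatches: int) -> bool:
    mm = 0
    for p, b in zip(pattern, window):
        if b not in IUPAC[p]:
            mm += 1
            if mm > max_mismatches:
                return False
    return True


def match_primer(template: str, primer: DegeneratePrimer,
                 max_mismatches: int = 0) -> list[tuple[int, str]]:
    """Find primer binding sites on both strands of *template*.

    Returns ``(position, strand)`` pairs, 0-based on the forward strand;
    strand "+" means the primer matches the template as written, "-" that it
    matches the reverse complement (the reported position is still the
    left-most template coordinate of the site). An N in the template is an
    unknown base and counts as a mismatch against every primer code.
    """
    template = template.upper()
    if set(template) - set("ACGTN"):
        raise ValueError("template may contain only ACGTN")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    pat_fwd = primer.sequence
    pat_rev = reverse_complement(primer.sequence)
    L = len(pat_fwd)
    sites: list[tuple[int, str]] = []
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        if _iupac_match(pat_fwd, window, max_mismatches):
            sites.append((i, "+"))
        if _iupac_match(pat_rev, window, max_mismatches):
            sites.append((i, "-"))
    return sites


def match_primer_bruteforce(template: str, primer: DegeneratePrimer,
                            max_mismatches: int = 0) -> list[tuple[int, str]]:
    """Reference scanner: expand every degenerate code and compare literally.

    Exponential in primer degeneracy; exists as an independent oracle for
    :func:`match_primer` and for tests only.
    """
    template = template.upper()
    L = len(primer.sequence)

    def expansions(pattern: str):
        return ("".join(p) for p in itertools.product(*(IUPAC[c] for c in pattern)))

    def hits(pattern: str) -> set[int]:
        out = set()
        for expanded in expansions(pattern):
            for i in range(len(template) - L + 1):
                mm = sum(a != b for a, b in zip(expanded, template[i:i + L]))
                if mm <= max_mismatches:
                    out.add(i)
        return out

    fwd = hits(primer.sequence)
    rev = hits(reverse_complement(primer.sequence))
    return sorted([(i, "+") for i in fwd] + [(i, "-") for i in rev])


def extract_amplicon(template: str, fwd: DegeneratePrimer, rev: DegeneratePrimer,
                     max_mismatches: int = 0, source_id: str = "") -> Amplicon:
    """Amplify *template* with a primer pair and orient by the labeled primer.

    Requires exactly one forward site on the plus strand and one reverse-primer
    site on the minus strand downstream of it. The amplicon records template
    bases where primer degeneracies meet the template, so restriction sites
    overlapping primer regions digest faithfully. If the labeled primer is the
    reverse one, the amplicon is returned reverse-complemented so the label
    sits at position 0.
    """
    template = template.upper()
    fwd_sites = [p for p, s in match_primer(template, fwd, max_mismatches) if s == "+"]
    if len(fwd_sites) != 1:
        raise PrimerSiteError(fwd.name, len(fwd_sites))
    start = fwd_sites[0]
    rev_sites = [p for p, s in match_primer(template, rev, max_mismatches)
                 if s == "-" and p >= start + len(fwd)]
    if len(rev_sites) != 1:
        raise PrimerSiteError(rev.name, len(rev_sites))
    end = rev_sites[0] + len(rev)  # half-open
    seq = template[start:end]
    if rev.labeled and not fwd.labeled:
        seq = reverse_complement(seq)
    return Amplicon(sequence=seq, source_id=source_id)


def predict_trf(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> TRFPrediction:
    """Length of the labeled terminal fragment: first cut from the 5' end.

    For palindromic sites a single-strand scan suffices; a non-palindromic
    enzyme is scanned on both strands and the earliest cut position wins.
    """
    seq = amplicon.sequence.upper()
    if not seq:
        raise ValueError("empty amplicon")
    rec = enzyme.recognition
    cut_positions = []
    i = seq.find(rec)
    if i >= 0:
        cut_positions.append(i + enzyme.cut_offset)
    if not enzyme.palindromic:
        rc = reverse_complement(rec)
        j = seq.find(rc)
        if j >= 0:
            # cut offset measured on the opposite strand maps to
            # len(rec) - cut_offset on this strand
            cut_positions.append(j + len(rec) - enzyme.cut_offset)
    if cut_positions:
        return TRFPrediction(enzyme.name, min(cut_positions), True)
    return TRFPrediction(enzyme.name, len(seq), False)


def predict_trf_bruteforce(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> TRFPrediction:
    """Position-by-position scan used as an independent oracle in tests."""
    seq = amplicon.sequence.upper()
    rec = enzyme.recognition
    for i in range(len(seq) - len(rec) + 1):
        if seq[i:i + len(rec)] == rec:
            return TRFPrediction(enzyme.name, i + enzyme.cut_offset, True)
    return TRFPrediction(enzyme.name, len(seq), False)


def digest_fragments(amplicon: Amplicon, enzyme: RestrictionEnzyme) -> list[int]:
    """All fragment lengths of a complete digest (labeled fragment first)."""
    seq = amplicon.sequence.upper()
    rec = enzyme.recognition
    cuts = []
    i = seq.find(rec)
    while i >= 0:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(rec, i + 1)
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def build_reference_db(records, taxon_labels, fwd: DegeneratePrimer,
                       rev: DegeneratePrimer, enzymes,
                       max_mismatches: int = 0):
    """Predict per-enzyme T-RFs for a set of reference sequences.

    ``records`` is an iterable of Biopython ``SeqRecord``-likes (``.id`` and
    ``.seq``); ``taxon_labels`` maps sequence id -> taxon label. Returns
    ``(taxa, failures)``: records whose amplification fails are reported in
    *failures* as ``(sequence_id, reason)`` rather than silently dropped.
    """
    taxa: list[ReferenceTaxon] = []
    failures: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate sequence_id {sid!r}")
        seen.add(sid)
        try:
            amp = extract_amplicon(str(rec.seq), fwd, rev,
                                   max_mismatches=max_mismatches, source_id=sid)
        except PrimerSiteError as exc:
            failures.append((sid, str(exc)))
            continue
        taxon = ReferenceTaxon(
            taxon_label=taxon_labels[sid] if not callable(taxon_labels) else taxon_labels(sid),
            sequence_id=sid,
        )
        for enz in enzymes:
            taxon.trf_by_enzyme[enz.name] = predict_trf(amp, enz).length_bp
        taxa.append(taxon)
    return taxa, failures


def refdb_to_frame(taxa: list[ReferenceTaxon]) -> pd.DataFrame:
    """Long-format table of the reference database (one row per enzyme)."""
    rows = [
        {"taxon_label": t.taxon_label, "sequence_id": t.sequence_id,
         "enzyme": enz, "trf_bp": trf}
        for t in taxa for enz, trf in sorted(t.trf_by_enzyme.items())
    ]
    return pd.DataFrame(rows, columns=["taxon_label", "sequence_id", "enzyme", "trf_bp"])


def refdb_from_frame(df: pd.DataFrame) -> list[ReferenceTaxon]:
    taxa = []
    for (label, sid), grp in df.groupby(["taxon_label", "sequence_id"], sort=False):
        taxa.append(ReferenceTaxon(label, sid,
                                   dict(zip(grp["enzyme"], grp["trf_bp"].astype(int)))))
    return taxa
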