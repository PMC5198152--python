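"""Mapping binned T-RFs to reference taxa, with dual-enzyme disambiguation.

A single 4-cutter digest cannot separate phylotypes whose terminal fragments
fall within sizing tolerance of each other (the classic case: two genera at
175 and 176 bp under HaeIII). A second digest with an enzyme cutting at a
different position resolves such collisions: a candidate taxon is credited
only if its second-enzyme fragment is actually observed in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .insilico import ReferenceTaxon
from .profiles import ROW_SUM_TOL, TRFMatrix


@dataclass
class Assignment:
    """Candidate taxa for one T-RF bin under one enzyme."""

    bin_bp: int
    enzyme_name: str
    candidate_taxa: list[str]
    status: str = field(init=False)

    def __post_init__(self):
        self.status = ("unassigned" if not self.candidate_taxa
                       else "unique" if len(self.candidate_taxa) == 1
                       else "ambiguous")


@dataclass
class ResolvedProfile:
    """Per-sample taxon abundances after collision resolution.

    ``unresolved_mass`` holds abundance that could not be attributed to any
    reference taxon (unassigned bins, or ambiguous bins whose candidates all
    lack second-enzyme support); assigned + unresolved always sums to 1.
    """

    sample_id: str
    taxon_abundance: dict[str, float]
    unresolved_mass: float = 0.0

    def __post_init__(self):
        total = sum(self.taxon_abundance.values()) + self.unresolved_mass
        if abs(total - 1.0) > ROW_SUM_TOL and total != 0.0:
            raise ValueError(f"mass not conserved for {self.sample_id!r}: {total}")


def assign_bins(matrix: TRFMatrix, refdb: list[ReferenceTaxon],
                tolerance_bp: float = 2.0) -> list[Assignment]:
    """List candidate taxa for each bin: every reference whose predicted
    T-RF under this enzyme lies within ``tolerance_bp`` of the bin center,
    sorted by distance then label."""
    if not refdb:
        raise ValueError("empty reference database")
    relevant = [t for t in refdb if matrix.enzyme_name in t.trf_by_enzyme]
    if not relevant:
        raise ValueError(f"no reference entries for enzyme {matrix.enzyme_name!r}")
    out = []
    for b in matrix.trf_bins:
        cands = sorted(
            (t for t in relevant
             if abs(t.trf_by_enzyme[matrix.enzyme_name] - b) <= tolerance_bp),
            key=lambda t: (abs(t.trf_by_enzyme[matrix.enzyme_name] - b), t.taxon_label),
        )
        out.append(Assignment(bin_bp=b, enzyme_name=matrix.enzyme_name,
                              candidate_taxa=[t.taxon_label for t in cands]))
    return out


def _taxon_mass(taxon: ReferenceTaxon, matrix: TRFMatrix, row: int,
                tolerance_bp: float) -> float:
    """Observed abundance in one sample's profile compatible with a taxon's
    predicted T-RF under that profile's enzyme."""
    trf = taxon.trf_by_enzyme[matrix.enzyme_name]
    mass = 0.0
    for j, b in enumerate(matrix.trf_bins):
        if abs(trf - b) <= tolerance_bp:
            mass += float(matrix.abundance[row, j])
    return mass


def dual_enzyme_resolve(primary: TRFMatrix, secondary: TRFMatrix,
                        refdb: list[ReferenceTaxon], tolerance_bp: float = 2.0,
                        split_rule: str = "proportional") -> list[ResolvedProfile]:
    """Resolve the primary-enzyme profile into taxon abundances using the
    secondary enzyme to break collisions.

    Unique bins transfer their full abundance to the single candidate.
    For an ambiguous bin, each candidate must be corroborated: its
    secondary-enzyme T-RF must carry nonzero abundance in the same sample's
    secondary profile. With ``split_rule="proportional"`` the bin's mass is
    divided among surviving candidates in proportion to their compatible
    secondary-bin abundances; with ``"report"`` multi-survivor bins are left
    unresolved rather than split. Mass with no surviving candidate is
    accumulated in ``unresolved_mass``.
    """
    if split_rule not in ("proportional", "report"):
        raise ValueError(f"unknown split_rule {split_rule!r}")
    if set(primary.sample_ids) != set(secondary.sample_ids):
        only = set(primary.sample_ids) ^ set(secondary.sample_ids)
        raise ValueError(f"samples present in one matrix only: {sorted(only)}")
    by_label: dict[str, ReferenceTaxon] = {}
    for t in refdb:
        if primary.enzyme_name not in t.trf_by_enzyme or \
           secondary.enzyme_name not in t.trf_by_enzyme:
            raise ValueError(f"taxon {t.taxon_label!r} lacks a T-RF for one enzyme")
        by_label[t.taxon_label] = t
    assignments = assign_bins(primary, refdb, tolerance_bp)
    sec_row = {s: i for i, s in enumerate(secondary.sample_ids)}
    profiles = []
    for i, sid in enumerate(primary.sample_ids):
        abund: dict[str, float] = {}
        unresolved = 0.0
        for j, asn in enumerate(assignments):
            mass = float(primary.abundance[i, j])
            if mass == 0.0:
                continue
            if asn.status == "unassigned":
                unresolved += mass
                continue
            if asn.status == "unique":
                label = asn.candidate_taxa[0]
                abund[label] = abund.get(label, 0.0) + mass
                continue
            support = {
                label: _taxon_mass(by_label[label], secondary, sec_row[sid], tolerance_bp)
                for label in asn.candidate_taxa
            }
            survivors = {lab: m for lab, m in support.items() if m > 0}
            if not survivors:
                unresolved += mass
            elif len(survivors) == 1:
                (label,) = survivors
                abund[label] = abund.get(label, 0.0) + mass
            elif split_rule == "proportional":
                total = sum(survivors.values())
                for label, m in survivors.items():
                    abund[label] = abund.get(label, 0.0) + mass * m / total
            else:
                unresolved += mass
        profiles.append(ResolvedProfile(sample_id=sid, taxon_abundance=abund,
                                        unresolved_mass=unresolved))
    return profiles


def profiles_to_frame(profiles: list[ResolvedProfile]) -> pd.DataFrame:
    """Samples x taxa abundance table with an ``_unresolved`` column."""
    taxa = sorted({lab for p in profiles for lab in p.taxon_abundance})
    rows = []
    for p in profiles:
        row = {lab: p.taxon_abundance.get(lab, 0.0) for lab in taxa}
        row["_unresolved"] = p.unresolved_mass
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index([p.sample_id for p in profiles],
                                             name="sample_id"))


def audit_table(matrix: TRFMatrix, refdb: list[ReferenceTaxon],
                tolerance_bp: float = 2.0) -> pd.DataFrame:
    """Assignment audit: one row per bin with candidates and status."""
    rows = [{"bin_bp": a.bin_bp, "enzyme": a.enzyme_name,
             "candidates": ";".join(a.candidate_taxa), "status": a.status}
            for a in assign_bins(matrix, refdb, tolerance_bp)]
    return pd.DataFrame(rows, columns=["bin_bp", "enzyme", "candidates", "status"])
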