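"""Synthetic study generator: reference sequences, community time series,
process parameters, and noisy triplicate peak tables with known ground truth.

The generator emulates an 11-reactor x 3-timepoint anaerobic-digester
monitoring design: per-reactor base communities over a panel of methanogen
phylotypes, bounded temporal drift, one reactor dominated (>0.9) by a single
hydrogenotroph (the high-ammonia regime in which acetoclastic methanogens
are suppressed), monotone couplings between chosen taxa and process
parameters, and capillary peak tables with sizing jitter and background
noise peaks. Every function is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico import (HAEIII, MCRA_REV, MLAS, MSPI, ReferenceTaxon,
                       extract_amplicon, predict_trf, reverse_complement)
from .profiles import Peak, PeakTable

# concrete degeneracy choices for the primer pair, free of HaeIII/MspI sites
_REV_REALIZED = "CGTTCATTGCGTAGTTAGGATAGT"   # mcrA-rev with B->T, V->A, R->A
_FWD_REALIZED = "GGTGGTGTAGGATTCACACAATA"    # mlas with M->A, D->A, M->A, R->A


@dataclass(frozen=True)
class TaxonSpec:
    """A synthetic phylotype: label plus target T-RF under each enzyme."""

    taxon_label: str
    haeIII_trf: int
    mspI_trf: int
    ambiguity_partner: str | None = None

    def __post_init__(self):
        for trf in (self.haeIII_trf, self.mspI_trf):
            if not 50 <= trf <= 500:
                raise ValueError(f"T-RF {trf} outside the 50-500 bp sizing window")


@dataclass(frozen=True)
class Coupling:
    taxon_label: str
    parameter: str
    sign: int       # +1 or -1
    strength: float  # target |Spearman rho| in (0, 1]

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not 0 < self.strength <= 1:
            raise ValueError("strength must be in (0, 1]")


# Parameter schema with plausible anaerobic-digester ranges (units in names
# where ambiguous): temperature degC, TAN/FAN g/L, VFA species g/L, OLR
# gVS/L/day, HRT days, SBP mL/gVS, CH4/CO2 volume %.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "temperature": (37.0, 55.0),
    "pH": (6.8, 8.2),
    "TAN": (1.0, 6.0),
    "FAN": (0.05, 0.75),
    "acid_capacity": (4.0, 20.0),
    "acetate": (0.1, 9.9),
    "propionate": (0.05, 4.1),
    "OLR": (0.5, 2.9),
    "HRT": (20.0, 80.0),
    "SBP": (250.0, 720.0),
    "CH4": (45.0, 65.0),
    "CO2": (35.0, 55.0),
}


@dataclass(frozen=True)
class StudyDesign:
    n_reactors: int = 11
    n_timepoints: int = 3
    couplings: tuple[Coupling, ...] = ()

    def __post_init__(self):
        params = [c.parameter for c in self.couplings]
        dup = {p for p in params if params.count(p) > 1}
        if dup:
            raise ValueError(f"conflicting couplings on parameters: {sorted(dup)}")
        unknown = {p for p in params if p not in PARAMETER_RANGES}
        if unknown:
            raise ValueError(f"couplings on parameters outside the schema: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"R{r+1}T{t+1}" for r in range(self.n_reactors)
                for t in range(self.n_timepoints)]


@dataclass
class GroundTruth:
    """Planted truth for one simulated study (regenerable from the seed)."""

    composition: pd.DataFrame          # samples x taxa, rows sum to 1
    parameter_table: pd.DataFrame | None
    seed: int
    realized_couplings: dict[str, float] = field(default_factory=dict)


def default_taxon_panel() -> list[TaxonSpec]:
    """Twelve methanogen phylotypes, including one deliberate HaeIII
    collision pair (175/176 bp, the acetoclast-vs-hydrogenotroph case)
    separated by >10 bp under MspI; all other T-RFs are >=5 bp apart and
    sit in [60, 490] bp, clear of the sizing-window edges."""
    specs = [
        TaxonSpec("Methanosarcina_A", 125, 102),
        TaxonSpec("Methanomethylovorans", 140, 119),
        TaxonSpec("Methanobrevibacter", 155, 135),
        TaxonSpec("Methanosaeta", 175, 420, ambiguity_partner="Methanoculleus_A"),
        TaxonSpec("Methanoculleus_A", 176, 230, ambiguity_partner="Methanosaeta"),
        TaxonSpec("Methanomassiliicoccales", 197, 150),
        TaxonSpec("Methanoculleus_B", 214, 165),
        TaxonSpec("Methanoregulaceae", 300, 244),
        TaxonSpec("Methanocorpusculum", 380, 258),
        TaxonSpec("Methanoculleus_C", 455, 272),
        TaxonSpec("Methanobacteriaceae", 468, 286),
        TaxonSpec("Methanosarcina_B", 489, 88),
    ]
    return specs


def default_couplings(strength: float = 0.8) -> tuple[Coupling, ...]:
    """Planted taxon-parameter couplings mirroring the qualitative pattern of
    ammonia-adapted hydrogenotrophs (positive with TAN) versus
    ammonia-sensitive acetoclasts (negative with FAN)."""
    return (
        Coupling("Methanoculleus_B", "TAN", +1, strength),
        Coupling("Methanosaeta", "FAN", -1, strength),
        Coupling("Methanobacteriaceae", "temperature", +1, strength),
        Coupling("Methanosarcina_B", "SBP", +1, strength),
        Coupling("Methanocorpusculum", "pH", -1, strength),
    )


def _scrub(seq: list[str], protected: set[int], rng: np.random.Generator,
           motifs=("GGCC", "CCGG")) -> None:
    """Mutate unprotected bases until no motif occurs outside protected spans."""
    for _ in range(200):
        dirty = False
        s = "".join(seq)
        for motif in motifs:
            start = s.find(motif)
            while start >= 0:
                span = range(start, start + len(motif))
                free = [i for i in span if i not in protected]
                if free:
                    i = free[0]
                    choices = [b for b in "ACT" if b != seq[i]]
                    seq[i] = choices[rng.integers(len(choices))]
                    dirty = True
                start = s.find(motif, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub confounding restriction sites")


def generate_reference_sequences(specs: list[TaxonSpec], amplicon_len: int = 520,
                                 seed: int = 0) -> list[SeqRecord]:
    """Build template sequences whose amplicons digest to the specified T-RFs.

    Each template carries exactly one mlas site and one mcrA-rev site; on
    the labeled (reverse-complement) strand the HaeIII and MspI recognition
    sites are planted so the first cut falls exactly at the specified T-RF
    length, with no confounding site anywhere else in the amplicon.
    """
    rng = np.random.default_rng(seed)
    fwd_len, rev_len = len(_FWD_REALIZED), len(_REV_REALIZED)
    records = []
    seen = set()
    for spec in specs:
        if spec.taxon_label in seen:
            raise ValueError(f"duplicate taxon label {spec.taxon_label!r}")
        seen.add(spec.taxon_label)
        hae_start = spec.haeIII_trf - HAEIII.cut_offset
        msp_start = spec.mspI_trf - MSPI.cut_offset
        for name, start in (("HaeIII", hae_start), ("MspI", msp_start)):
            if start < rev_len or start + 4 > amplicon_len - fwd_len:
                raise ValueError(f"{spec.taxon_label}: {name} site at {start} falls "
                                 "inside a primer region or beyond the amplicon")
        if abs(hae_start - msp_start) < 4:
            raise ValueError(f"{spec.taxon_label}: HaeIII and MspI sites overlap")
        # labeled-strand amplicon: [rev primer][random core][rc of fwd primer]
        core_len = amplicon_len - fwd_len - rev_len
        labeled = list(_REV_REALIZED
                       + "".join(rng.choice(list("ACGT"), size=core_len))
                       + reverse_complement(_FWD_REALIZED))
        labeled[hae_start:hae_start + 4] = HAEIII.recognition
        labeled[msp_start:msp_start + 4] = MSPI.recognition
        protected = set(range(hae_start, hae_start + 4)) | \
            set(range(msp_start, msp_start + 4)) | \
            set(range(rev_len)) | set(range(amplicon_len - fwd_len, amplicon_len))
        _scrub(labeled, protected, rng)
        template = reverse_complement("".join(labeled))
        # round-trip verification against the in-silico digest
        amp = extract_amplicon(template, MLAS, MCRA_REV, source_id=spec.taxon_label)
        for enzyme, want in ((HAEIII, spec.haeIII_trf), (MSPI, spec.mspI_trf)):
            got = predict_trf(amp, enzyme)
            if not got.cut_found or got.length_bp != want:
                raise RuntimeError(f"{spec.taxon_label}: planted {enzyme.name} T-RF "
                                   f"{want} but digest predicts {got.length_bp}")
        records.append(SeqRecord(Seq(template), id=spec.taxon_label, description=""))
    return records


def reference_db_from_specs(specs: list[TaxonSpec]) -> list[ReferenceTaxon]:
    """Reference T-RF database straight from the specs (bypassing sequences)."""
    return [ReferenceTaxon(s.taxon_label, s.taxon_label,
                           {HAEIII.name: s.haeIII_trf, MSPI.name: s.mspI_trf})
            for s in specs]


def generate_community_series(design: StudyDesign, taxon_labels: list[str],
                              seed: int = 0, dominated_reactor: int = 0,
                              dominant_taxon: str | None = None) -> GroundTruth:
    """Compositional time series with reactor-specific structure.

    Non-dominated reactors draw a Dirichlet base composition mixed with a
    uniform floor (so every panel taxon is present at >=0.3% in every
    sample, as fingerprinting panels are built from taxa actually detected
    across the study), then drift via a bounded multiplicative random walk
    between timepoints. One reactor is dominated (>0.9 at every timepoint)
    by a single taxon, emulating the ammonia-stressed regime where minor
    taxa stay below 1%.
    """
    k = len(taxon_labels)
    if k < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    if dominant_taxon is None:
        dominant_taxon = taxon_labels[4 % k]
    dom_idx = taxon_labels.index(dominant_taxon)
    rows, ids = [], []
    for r in range(design.n_reactors):
        if r == dominated_reactor:
            for t in range(design.n_timepoints):
                top = rng.uniform(0.94, 0.96)
                tail = (1 - top) * (0.8 / (k - 1) + 0.2 * rng.dirichlet(np.full(k - 1, 10.0)))
                x = np.insert(tail, dom_idx, top)
                rows.append(x / x.sum())
                ids.append(f"R{r+1}T{t+1}")
            continue
        base = 0.95 * rng.dirichlet(np.full(k, 2.0)) + 0.05 / k
        x = base
        for t in range(design.n_timepoints):
            if t > 0:
                drift = np.clip(np.exp(rng.normal(0.0, 0.15, size=k)), 0.8, 1.25)
                x = x * drift
                x = x / x.sum()
                x = 0.96 * x + 0.04 / k
            rows.append(x / x.sum())
            ids.append(f"R{r+1}T{t+1}")
    comp = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=taxon_labels)
    comp = comp.loc[design.sample_ids]
    return GroundTruth(composition=comp, parameter_table=None, seed=seed)


def generate_process_parameters(truth: GroundTruth, design: StudyDesign,
                                noise_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Process-parameter table with planted monotone couplings.

    A coupled parameter is a monotone (rank-preserving affine) transform of
    the named taxon's normal-scored abundance plus Gaussian noise scaled so
    the expected Spearman correlation matches the coupling strength at
    ``noise_sd = 1`` and tends to +-1 as ``noise_sd -> 0``. Uncoupled
    parameters are independent uniform draws over their plausible range.
    Realized rank correlations are recorded on the GroundTruth.
    """
    rng = np.random.default_rng(seed)
    comp = truth.composition
    n = len(comp)
    coupled = {c.parameter: c for c in design.couplings}
    data = {}
    for param, (lo, hi) in PARAMETER_RANGES.items():
        if param in coupled:
            c = coupled[param]
            a = comp[c.taxon_label].to_numpy()
            ranks = pd.Series(a).rank(method="average").to_numpy()
            z = _normal_scores(ranks, n)
            rho_p = 2 * np.sin(np.pi * c.strength / 6)
            sigma = np.sqrt(max(1.0 / rho_p ** 2 - 1.0, 0.0)) * noise_sd
            raw = c.sign * z + sigma * rng.standard_normal(n)
            data[param] = _rescale(raw, lo, hi)
        else:
            data[param] = rng.uniform(lo, hi, size=n)
    table = pd.DataFrame(data, index=comp.index)
    for c in design.couplings:
        rho = comp[c.taxon_label].corr(table[c.parameter], method="spearman")
        truth.realized_couplings[f"{c.taxon_label}~{c.parameter}"] = float(rho)
    truth.parameter_table = table
    return table


def _normal_scores(ranks: np.ndarray, n: int) -> np.ndarray:
    from scipy.stats import norm
    return norm.ppf((ranks - 0.375) / (n + 0.25))


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, (lo + hi) / 2)
    return lo + (x - x.min()) / span * (hi - lo)


def simulate_peak_tables(truth: GroundTruth, refdb: list[ReferenceTaxon],
                         sizing_sd: float = 0.3, n_noise_peaks: int = 30,
                         noise_area_frac: float = 0.005, n_replicates: int = 3,
                         seed: int = 0, total_signal: float = 50_000.0,
                         return_labels: bool = False):
    """Triplicate peak tables per sample and enzyme with planted structure.

    Each replicate carries one true peak per taxon at the reference T-RF
    plus independent Gaussian sizing jitter, area proportional to the
    planted abundance, plus ``n_noise_peaks`` background peaks uniform over
    the 50-500 bp window with areas uniform on (0, noise_area_frac x the
    largest true peak area]. With ``return_labels`` the function also
    returns, per table, the taxon label behind each peak (None for noise),
    so tests can audit exactly which peaks a filter removed.
    """
    if sizing_sd < 0:
        raise ValueError("sizing_sd must be >= 0")
    if not 0 <= noise_area_frac <= 0.05:
        raise ValueError("noise_area_frac must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    enzymes = sorted({e for t in refdb for e in t.trf_by_enzyme})
    trf = {(t.taxon_label, e): t.trf_by_enzyme[e] for t in refdb for e in t.trf_by_enzyme}
    tables = []
    label_lists: list[list] = []
    for sid, row in truth.composition.iterrows():
        for enzyme in enzymes:
            for rep in range(1, n_replicates + 1):
                scale = total_signal * rng.uniform(0.9, 1.1)
                entries = []
                for label, abundance in row.items():
                    if abundance <= 0:
                        continue
                    size = trf[(label, enzyme)] + (rng.normal(0.0, sizing_sd)
                                                   if sizing_sd > 0 else 0.0)
                    entries.append((Peak(size_bp=float(size),
                                         area=float(abundance * scale)), label))
                if n_noise_peaks and noise_area_frac > 0:
                    cap = noise_area_frac * max(p.area for p, _ in entries)
                    for _ in range(n_noise_peaks):
                        entries.append((Peak(size_bp=float(rng.uniform(50.0, 500.0)),
                                             area=float(rng.uniform(0.0, cap))), None))
                entries.sort(key=lambda e: e[0].size_bp)
                tables.append(PeakTable(sample_id=str(sid), replicate=rep,
                                        enzyme_name=enzyme,
                                        peaks=[p for p, _ in entries]))
                label_lists.append([lab for _, lab in entries])
    return (tables, label_lists) if return_labels else tables


def simulate_study(seed: int = 0, *, n_taxa: int = 12, design: StudyDesign | None = None,
                   sizing_sd: float = 0.3, n_noise_peaks: int = 30,
                   noise_area_frac: float = 0.005, n_replicates: int = 3,
                   noise_sd: float = 1.0):
    """One call producing a complete synthetic study.

    Returns ``(truth, specs, refdb, peak_tables)`` with sub-seeds derived
    deterministically from ``seed``.
    """
    specs = default_taxon_panel()[:n_taxa]
    if len(specs) < n_taxa:
        raise ValueError(f"panel supports up to {len(default_taxon_panel())} taxa")
    if design is None:
        design = StudyDesign(couplings=default_couplings())
    labels = [s.taxon_label for s in specs]
    missing = {c.taxon_label for c in design.couplings} - set(labels)
    if missing:
        raise ValueError(f"couplings name taxa outside the panel: {sorted(missing)}")
    ss = np.random.SeedSequence(seed).spawn(3)
    truth = generate_community_series(design, labels,
                                      seed=int(ss[0].generate_state(1)[0] % 2**31))
    generate_process_parameters(truth, design, noise_sd=noise_sd,
                                seed=int(ss[1].generate_state(1)[0] % 2**31))
    refdb = reference_db_from_specs(specs)
    tables = simulate_peak_tables(truth, refdb, sizing_sd=sizing_sd,
                                  n_noise_peaks=n_noise_peaks,
                                  noise_area_frac=noise_area_frac,
                                  n_replicates=n_replicates,
                                  seed=int(ss[2].generate_state(1)[0] % 2**31))
    return truth, specs, refdb, tables
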