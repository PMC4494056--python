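"""Fully specified toy multi-species dataset with known ground truth.

Every species genome is the same random ancestral sequence plus the TE
insertions accumulated on its lineage: an ``ancestral``-branch insertion
is present in every species, a ``primate``-branch insertion in every
primate (including human), and a ``human``-branch insertion in human
only.  Because every difference between genomes is a tracked insertion,
the emitted pairwise chains are *exact* — block/gap structure mirrors
the insertion ledger — which isolates downstream classifier logic from
aligner noise.

Binding-site windows are planted fully inside insertions of the branch
matching their intended lineage label (so a human-specific window has,
by construction, zero chain coverage in every non-human species), or
inside shared sequence for ``shared`` sites.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core_genomics import (
    AlignmentChain,
    BindingSite,
    GenomicInterval,
    IntervalSet,
    MethylCall,
    RepeatAnnotation,
    write_bed,
    write_chain,
    write_fasta,
    write_gene_table,
    write_methylation,
    write_repeat_bed,
    write_sites_bed,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genomes",
    "emit_chains",
    "plant_features",
    "simulate_individual_presence",
    "simulate_cohort",
]

BRANCH_ANCESTRAL = "ancestral"
BRANCH_PRIMATE = "primate"
BRANCH_HUMAN = "human"

RODENTS = ("mouse", "rat")
PRIMATES = ("chimp", "gorilla", "orangutan", "gibbon", "rhesus", "marmoset")
HUMAN = "human"

_BRANCHES_BY_SPECIES: Dict[str, Tuple[str, ...]] = {
    **{sp: (BRANCH_ANCESTRAL,) for sp in RODENTS},
    **{sp: (BRANCH_ANCESTRAL, BRANCH_PRIMATE) for sp in PRIMATES},
    HUMAN: (BRANCH_ANCESTRAL, BRANCH_PRIMATE, BRANCH_HUMAN),
}

# TE family geometry: (full length draw range, truncated length range)
_FAMILY_GEOMETRY = {
    "L1": ((5962, 6189), (1000, 2500)),
    "LTR7": ((450, 450), (450, 450)),
    "LTR5": ((600, 600), (600, 600)),
}

# RepeatMasker-style names per (family, branch) for the human annotation track
_FAMILY_NAMES = {
    ("L1", BRANCH_HUMAN): ("L1HS", "L1PA2"),
    ("L1", BRANCH_PRIMATE): ("L1PA4",),
    ("L1", BRANCH_ANCESTRAL): ("L1PA7",),
    ("LTR7", BRANCH_HUMAN): ("LTR7",),
    ("LTR7", BRANCH_PRIMATE): ("LTR7",),
    ("LTR7", BRANCH_ANCESTRAL): ("LTR7B",),
    ("LTR5", BRANCH_HUMAN): ("LTR5_Hs",),
    ("LTR5", BRANCH_PRIMATE): ("LTR5A",),
    ("LTR5", BRANCH_ANCESTRAL): ("LTR5B",),
}

_FAMILY_CLASS = {"L1": "LINE", "LTR7": "LTR", "LTR5": "LTR"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; identical seed => identical files."""

    seed: int = 0
    chrom_name: str = "chr1"
    genome_length_bp: int = 2_000_000
    window_width: int = 200
    peak_width: int = 100

    # lineage split times (years), for provenance and rate modelling
    split_years: Dict[str, float] = field(default_factory=lambda: {
        "rodent_primate": 75_000_000,
        "human_chimp": 13_000_000,
        "modern_archaic": 370_000,
    })

    # insertions per branch per TE family
    te_insertions: Dict[str, Dict[str, int]] = field(default_factory=lambda: {
        BRANCH_HUMAN: {"L1": 12, "LTR7": 8, "LTR5": 6},
        BRANCH_PRIMATE: {"L1": 10, "LTR7": 8, "LTR5": 4},
        BRANCH_ANCESTRAL: {"L1": 8, "LTR7": 4, "LTR5": 2},
    })
    l1_truncated_fraction: float = 0.15
    divergence_pct: Dict[str, float] = field(default_factory=lambda: {
        BRANCH_HUMAN: 0.5, BRANCH_PRIMATE: 3.0, BRANCH_ANCESTRAL: 8.0,
    })

    # planted binding sites
    n_sites_per_tf: Dict[str, int] = field(default_factory=lambda: {
        "NANOG": 60, "CTCF": 60, "POU5F1": 60,
    })
    label_fractions: Dict[str, float] = field(default_factory=lambda: {
        "human_specific": 0.2, "primate_specific": 0.3, "shared": 0.5,
    })
    shared_in_te_fraction: float = 0.4

    # domains
    lad_fraction: float = 0.429
    pmd_fraction: float = 0.37
    n_lads: int = 8
    n_pmds: int = 8

    # 5hmC
    hmc_site_fraction: Dict[str, float] = field(default_factory=lambda: {
        "NANOG": 0.46, "CTCF": 0.15, "POU5F1": 0.15,
    })
    n_background_hmc: int = 60

    # genes & planted proximity excess
    n_fast_genes: int = 12
    n_slow_genes: int = 12
    gene_length_bp: int = 2_000
    gene_flank_bp: int = 5_000
    proximity_threshold_bp: float = 5_000.0
    proximity_base_rate: float = 2.0
    proximity_effect: float = 3.0

    # per-individual conservation rates
    conservation_rates: Dict[str, float] = field(default_factory=lambda: {
        "papua": 0.314, "han": 0.357, "yoruba": 0.392,
        "french": 0.433, "san": 0.436,
    })
    archaic_rates: Dict[str, float] = field(default_factory=lambda: {
        "neand_1": 0.03, "neand_2": 0.04, "neand_3": 0.05,
    })

    def validate(self) -> None:
        for rates in (self.conservation_rates, self.archaic_rates):
            if any(not 0 <= r <= 1 for r in rates.values()):
                raise ValueError("conservation rates must lie in [0, 1]")
        if abs(sum(self.label_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("label fractions must sum to 1")
        if any(t <= 0 for t in self.split_years.values()):
            raise ValueError("split times must be positive")
        total_insert = sum(
            n * _FAMILY_GEOMETRY[fam][0][1]
            for branch in self.te_insertions.values() for fam, n in branch.items())
        reserved = (self.n_fast_genes + self.n_slow_genes) * (
            self.gene_length_bp + 2 * self.gene_flank_bp)
        if total_insert + reserved > 0.6 * self.genome_length_bp:
            raise ValueError("insertion + gene load exceeds genome capacity")


@dataclass
class Insertion:
    insertion_id: int
    branch: str
    family: str
    anc_offset: int
    sequence: str
    full_length: bool
    annotation_name: str


@dataclass
class SyntheticCohort:
    """Everything the simulation produced, in memory, plus ``write()``."""

    config: SimulationConfig
    genomes: Dict[str, Dict[str, str]]
    insertions: List[Insertion]
    human_insertion_spans: Dict[int, Tuple[int, int]]
    chains: Dict[str, List[AlignmentChain]]
    alt_assembly_chains: List[AlignmentChain]
    sites: List[BindingSite] = field(default_factory=list)
    ground_truth: Optional[pd.DataFrame] = None
    repeats: List[RepeatAnnotation] = field(default_factory=list)
    lads: Optional[IntervalSet] = None
    pmds: Optional[IntervalSet] = None
    methyl_calls: List[MethylCall] = field(default_factory=list)
    genes: Optional[pd.DataFrame] = None
    presence: Optional[pd.DataFrame] = None

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for species, chroms in sorted(self.genomes.items()):
            write_fasta(str(out / f"{species}.fa"), chroms)
        for species, chains in sorted(self.chains.items()):
            write_chain(str(out / f"human_to_{species}.chain"), chains)
        write_chain(str(out / "human_alt.chain"), self.alt_assembly_chains)
        write_sites_bed(str(out / "sites.bed"), self.sites)
        write_repeat_bed(str(out / "rmsk.bed"), self.repeats)
        if self.lads is not None:
            write_bed(str(out / "lads.bed"), self.lads, six_col=False)
        if self.pmds is not None:
            write_bed(str(out / "pmds.bed"), self.pmds, six_col=False)
        write_methylation(str(out / "hmc.tsv"), self.methyl_calls)
        if self.genes is not None:
            write_gene_table(str(out / "genes.tsv"), self.genes)
        if self.presence is not None:
            self.presence.to_csv(out / "presence.tsv", sep="\t",
                                 index_label="site_id")
        if self.ground_truth is not None:
            self.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.config.seed,
                            "genome_length_bp": self.config.genome_length_bp,
                            "chrom_name": self.config.chrom_name}, fh)

    def bundle_hash(self) -> str:
        """Stable content hash of the in-memory bundle (determinism checks)."""
        h = hashlib.sha256()
        for sp in sorted(self.genomes):
            for chrom in sorted(self.genomes[sp]):
                h.update(self.genomes[sp][chrom].encode())
        if self.ground_truth is not None:
            h.update(self.ground_truth.to_csv(index=False).encode())
        if self.presence is not None:
            h.update(self.presence.to_csv().encode())
        return h.hexdigest()


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate_copy(rng: np.random.Generator, seq: str, divergence_pct: float) -> str:
    n_mut = rng.binomial(len(seq), divergence_pct / 100.0)
    if n_mut == 0:
        return seq
    chars = list(seq)
    for i in rng.choice(len(seq), size=n_mut, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Stage 1: genomes

def simulate_genomes(config: SimulationConfig) -> SyntheticCohort:
    """Ancestral sequence + branch-tracked TE insertions, per species."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.genome_length_bp
    chrom = config.chrom_name
    ancestral = _random_dna(rng, L)

    # fixed per-seed consensus sequence per family
    consensus: Dict[str, str] = {}
    for fam, ((full_lo, full_hi), _) in sorted(_FAMILY_GEOMETRY.items()):
        consensus[fam] = _random_dna(rng, full_hi)

    # gene regions are reserved before insertion placement so proximity
    # planting later has insertion-free space to work in
    n_genes = config.n_fast_genes + config.n_slow_genes
    slot = L // (n_genes + 1)
    region_width = config.gene_length_bp + 2 * config.gene_flank_bp
    reserved: List[Tuple[int, int]] = []
    for i in range(n_genes):
        start = (i + 1) * slot - region_width // 2
        reserved.append((start, start + region_width))

    def in_reserved(pos: int) -> bool:
        return any(s - 400 <= pos < e + 400 for s, e in reserved)

    insertions: List[Insertion] = []
    taken: List[int] = []
    next_id = 0
    for branch in (BRANCH_ANCESTRAL, BRANCH_PRIMATE, BRANCH_HUMAN):
        for fam in sorted(config.te_insertions.get(branch, {})):
            (full_lo, full_hi), (tr_lo, tr_hi) = _FAMILY_GEOMETRY[fam]
            names = _FAMILY_NAMES[(fam, branch)]
            for _ in range(config.te_insertions[branch][fam]):
                full = (fam != "L1"
                        or rng.random() >= config.l1_truncated_fraction)
                length = (int(rng.integers(full_lo, full_hi + 1)) if full
                          else int(rng.integers(tr_lo, tr_hi + 1)))
                seq = _mutate_copy(rng, consensus[fam][:length],
                                   config.divergence_pct[branch])
                for _attempt in range(10_000):
                    off = int(rng.integers(2_000, L - 2_000))
                    if not in_reserved(off) and all(abs(off - t) > 400 for t in taken):
                        break
                else:  # pragma: no cover - config error path
                    raise ValueError("could not place insertion; genome too crowded")
                taken.append(off)
                insertions.append(Insertion(
                    insertion_id=next_id, branch=branch, family=fam,
                    anc_offset=off, sequence=seq, full_length=full,
                    annotation_name=str(names[rng.integers(0, len(names))])))
                next_id += 1
    insertions.sort(key=lambda i: i.anc_offset)

    genomes: Dict[str, Dict[str, str]] = {}
    human_spans: Dict[int, Tuple[int, int]] = {}
    for species, branches in _BRANCHES_BY_SPECIES.items():
        parts: List[str] = []
        pos = 0
        out_len = 0
        for ins in insertions:
            parts.append(ancestral[pos:ins.anc_offset])
            out_len += ins.anc_offset - pos
            pos = ins.anc_offset
            if ins.branch in branches:
                if species == HUMAN:
                    human_spans[ins.insertion_id] = (out_len, out_len + len(ins.sequence))
                parts.append(ins.sequence)
                out_len += len(ins.sequence)
        parts.append(ancestral[pos:])
        genomes[species] = {chrom: "".join(parts)}

    cohort = SyntheticCohort(
        config=config, genomes=genomes, insertions=insertions,
        human_insertion_spans=human_spans, chains={}, alt_assembly_chains=[])
    cohort._ancestral = ancestral  # type: ignore[attr-defined]
    cohort._reserved_gene_regions = reserved  # type: ignore[attr-defined]
    cohort._rng_state = rng  # type: ignore[attr-defined]
    return cohort


# ---------------------------------------------------------------------------
# Stage 2: chains

def _pair_chain(
    chrom: str,
    ancestral_len: int,
    insertions: Sequence[Insertion],
    branches_a: Tuple[str, ...],
    branches_b: Tuple[str, ...],
    len_a: int,
    len_b: int,
    chain_id: int,
) -> AlignmentChain:
    """Exact chain from genome A (target) to genome B (subject)."""
    blocks: List[Tuple[int, int, int]] = []
    cur = 0
    dt = dq = 0
    pos = 0

    def push_shared(length: int) -> None:
        nonlocal cur, dt, dq
        if length == 0:
            return
        if (dt or dq) and cur:
            blocks.append((cur, dt, dq))
            cur, dt, dq = 0, 0, 0
        cur += length

    for ins in insertions:
        push_shared(ins.anc_offset - pos)
        pos = ins.anc_offset
        in_a = ins.branch in branches_a
        in_b = ins.branch in branches_b
        if in_a and in_b:
            push_shared(len(ins.sequence))
        elif in_a:
            dt += len(ins.sequence)
        elif in_b:
            dq += len(ins.sequence)
    push_shared(ancestral_len - pos)
    blocks.append((cur, 0, 0))

    return AlignmentChain(
        chain_id=chain_id, score=sum(b[0] for b in blocks),
        t_name=chrom, t_size=len_a, t_strand="+", t_start=0, t_end=len_a,
        q_name=chrom, q_size=len_b, q_strand="+", q_start=0, q_end=len_b,
        blocks=blocks)


def emit_chains(cohort: SyntheticCohort) -> SyntheticCohort:
    """Exact human->species chains plus a same-genome alt-assembly chain."""
    config = cohort.config
    chrom = config.chrom_name
    human_len = len(cohort.genomes[HUMAN][chrom])
    for i, species in enumerate(sorted(set(RODENTS) | set(PRIMATES))):
        other_len = len(cohort.genomes[species][chrom])
        cohort.chains[species] = [_pair_chain(
            chrom, config.genome_length_bp, cohort.insertions,
            _BRANCHES_BY_SPECIES[HUMAN], _BRANCHES_BY_SPECIES[species],
            human_len, other_len, chain_id=i + 1)]
    cohort.alt_assembly_chains = [AlignmentChain(
        chain_id=100, score=human_len, t_name=chrom, t_size=human_len,
        t_strand="+", t_start=0, t_end=human_len, q_name=chrom,
        q_size=human_len, q_strand="+", q_start=0, q_end=human_len,
        blocks=[(human_len, 0, 0)])]
    return cohort


# ---------------------------------------------------------------------------
# Stage 3: planted features

_LABELS = ("human_specific", "primate_specific", "shared")
_LABEL_BRANCH = {"human_specific": BRANCH_HUMAN, "primate_specific": BRANCH_PRIMATE}


def _anc_to_human(insertions: Sequence[Insertion],
                  spans: Dict[int, Tuple[int, int]], x: int) -> int:
    shift = 0
    for ins in insertions:
        if ins.anc_offset <= x and ins.insertion_id in spans:
            shift += len(ins.sequence)
    return x + shift


def plant_features(cohort: SyntheticCohort) -> SyntheticCohort:
    """Plant sites, repeat annotations, domains, hmC calls and genes."""
    config = cohort.config
    rng: np.random.Generator = cohort._rng_state  # type: ignore[attr-defined]
    chrom = config.chrom_name
    human_len = len(cohort.genomes[HUMAN][chrom])
    w = config.window_width
    half_peak = config.peak_width // 2

    # repeat annotation track over the human genome
    cohort.repeats = [
        RepeatAnnotation(
            interval=GenomicInterval(chrom, s, e, "+", ins.annotation_name),
            repeat_name=ins.annotation_name,
            repeat_class=_FAMILY_CLASS[ins.family],
            divergence_pct=config.divergence_pct[ins.branch])
        for ins in cohort.insertions
        for s, e in [cohort.human_insertion_spans.get(ins.insertion_id, (None, None))]
        if s is not None
    ]

    by_branch: Dict[str, List[Insertion]] = {}
    for ins in cohort.insertions:
        if ins.insertion_id in cohort.human_insertion_spans \
                and len(ins.sequence) >= w + 40:
            by_branch.setdefault(ins.branch, []).append(ins)

    # liftable ancestral chunks in human coordinates (for shared sites)
    chunks: List[Tuple[int, int]] = []
    pos_anc = 0
    for ins in cohort.insertions:
        h_start = _anc_to_human(cohort.insertions, cohort.human_insertion_spans, pos_anc)
        h_end = h_start + (ins.anc_offset - pos_anc)
        if h_end - h_start >= w + 40:
            chunks.append((h_start, h_end))
        pos_anc = ins.anc_offset
    h_start = _anc_to_human(cohort.insertions, cohort.human_insertion_spans, pos_anc)
    chunks.append((h_start, h_start + (config.genome_length_bp - pos_anc)))

    reserved = cohort._reserved_gene_regions  # type: ignore[attr-defined]
    reserved_h = [(
        _anc_to_human(cohort.insertions, cohort.human_insertion_spans, s),
        _anc_to_human(cohort.insertions, cohort.human_insertion_spans, e))
        for s, e in reserved]

    def outside_reserved(pos: int) -> bool:
        return not any(s <= pos < e for s, e in reserved_h)

    def make_site(tf: str, mid: int, idx: int) -> BindingSite:
        peak = GenomicInterval(chrom, mid - half_peak, mid + half_peak)
        return BindingSite(tf=tf, peak=peak, window_width=w,
                           site_id=f"{tf}_{idx:04d}")

    gt_rows: List[Dict[str, object]] = []
    sites: List[BindingSite] = []
    idx = 0
    for tf in sorted(config.n_sites_per_tf):
        n = config.n_sites_per_tf[tf]
        counts = {label: int(round(config.label_fractions[label] * n))
                  for label in _LABELS}
        counts["shared"] = n - counts["human_specific"] - counts["primate_specific"]
        for label in _LABELS:
            for _ in range(counts[label]):
                if label in _LABEL_BRANCH:
                    pool = by_branch.get(_LABEL_BRANCH[label], [])
                    if not pool:
                        raise ValueError(f"no insertions to host {label} sites")
                    ins = pool[rng.integers(0, len(pool))]
                    s, e = cohort.human_insertion_spans[ins.insertion_id]
                    mid = int(rng.integers(s + w // 2 + 10, e - w // 2 - 10))
                    family = ins.annotation_name
                    ins_id: Optional[int] = ins.insertion_id
                else:
                    in_te = rng.random() < config.shared_in_te_fraction
                    pool = by_branch.get(BRANCH_ANCESTRAL, []) if in_te else None
                    if in_te and pool:
                        ins = pool[rng.integers(0, len(pool))]
                        s, e = cohort.human_insertion_spans[ins.insertion_id]
                        mid = int(rng.integers(s + w // 2 + 10, e - w // 2 - 10))
                        family, ins_id = ins.annotation_name, ins.insertion_id
                    else:
                        for _attempt in range(10_000):
                            c_s, c_e = chunks[rng.integers(0, len(chunks))]
                            mid = int(rng.integers(c_s + w // 2 + 10,
                                                   c_e - w // 2 - 10))
                            if outside_reserved(mid):
                                break
                        family, ins_id = None, None
                site = make_site(tf, mid, idx)
                idx += 1
                sites.append(site)
                gt_rows.append({
                    "site_id": site.site_id, "tf": tf, "chrom": chrom,
                    "midpoint": mid, "label": label, "te_family": family,
                    "insertion_id": ins_id, "role": "core", "gene_id": None})

    # genes + planted proximity excess (extra shared sites near gene spans)
    gene_rows: List[Dict[str, object]] = []
    anc2h = lambda x: _anc_to_human(cohort.insertions, cohort.human_insertion_spans, x)
    n_genes = config.n_fast_genes + config.n_slow_genes
    gene_classes = (["fast"] * config.n_fast_genes + ["slow"] * config.n_slow_genes)
    for g, ((r_s, r_e), g_class) in enumerate(zip(reserved, gene_classes)):
        g_start_anc = r_s + config.gene_flank_bp
        g_start = anc2h(g_start_anc)
        g_end = g_start + config.gene_length_bp
        ka_ks = (float(rng.normal(0.6, 0.05)) if g_class == "fast"
                 else float(rng.normal(0.1, 0.02)))
        gene_id = f"gene_{g_class}_{g:03d}"
        gene_rows.append({"gene_id": gene_id, "chrom": chrom, "start": g_start,
                          "end": g_end, "gene_class": g_class,
                          "ka_ks": round(max(ka_ks, 0.01), 3)})
        lam = config.proximity_base_rate * (
            config.proximity_effect if g_class == "fast" else 1.0)
        for _ in range(int(rng.poisson(lam))):
            offset = int(rng.integers(100, int(config.proximity_threshold_bp) - 500))
            side = -1 if rng.random() < 0.5 else 1
            mid = g_start - offset if side < 0 else g_end + offset
            site = make_site("NANOG", mid, idx)
            idx += 1
            sites.append(site)
            gt_rows.append({
                "site_id": site.site_id, "tf": "NANOG", "chrom": chrom,
                "midpoint": mid, "label": "shared", "te_family": None,
                "insertion_id": None, "role": "proximity_filler",
                "gene_id": gene_id})
    cohort.genes = pd.DataFrame(gene_rows)

    # LADs / PMDs: n equal-length segments hitting the target fraction exactly
    def domain_set(fraction: float, n_domains: int, name: str) -> IntervalSet:
        total = int(round(fraction * human_len))
        length = total // n_domains
        lengths = [length] * (n_domains - 1) + [total - length * (n_domains - 1)]
        free = human_len - total
        gaps = rng.dirichlet(np.ones(n_domains + 1)) * free
        out = IntervalSet(genome_size={chrom: human_len}, name=name)
        pos = 0
        for i, dlen in enumerate(lengths):
            pos += int(gaps[i])
            out.add(GenomicInterval(chrom, pos, pos + dlen))
            pos += dlen
        return out

    cohort.lads = domain_set(config.lad_fraction, config.n_lads, "lads")
    cohort.pmds = domain_set(config.pmd_fraction, config.n_pmds, "pmds")

    # 5hmC: a strand-asymmetric triple within 50 bp of a fraction of sites
    calls: List[MethylCall] = []
    for site in sites:
        frac = config.hmc_site_fraction.get(site.tf, 0.0)
        if rng.random() < frac:
            anchor = site.midpoint + int(rng.integers(-30, 15))
            spacing = int(rng.integers(6, 14))
            for j, strand in enumerate(("+", "-", "+")):
                calls.append(MethylCall(chrom, anchor + j * spacing, strand,
                                        "CG", "hmC",
                                        round(float(rng.uniform(20, 80)), 1)))
    for _ in range(config.n_background_hmc):
        pos = int(rng.integers(0, human_len))
        strand = "+" if rng.random() < 0.5 else "-"
        calls.append(MethylCall(chrom, pos, strand, "CG", "hmC",
                                round(float(rng.uniform(20, 80)), 1)))
    calls.sort(key=lambda c: (c.chrom, c.position, c.strand))
    cohort.methyl_calls = calls

    cohort.sites = sites
    cohort.ground_truth = pd.DataFrame(gt_rows)
    return cohort


# ---------------------------------------------------------------------------
# Stage 4: individual presence

def simulate_individual_presence(cohort: SyntheticCohort) -> pd.DataFrame:
    """Bernoulli presence of each human-specific site per individual genome."""
    config = cohort.config
    if cohort.ground_truth is None:
        raise ValueError("plant_features must run first")
    hs = cohort.ground_truth[cohort.ground_truth.label == "human_specific"]
    if hs.empty:
        raise ValueError("no human-specific sites to score")
    rng = np.random.default_rng(config.seed + 1)
    data: Dict[str, List[int]] = {}
    for name, rate in list(config.conservation_rates.items()) + \
            list(config.archaic_rates.items()):
        data[name] = (rng.random(len(hs)) < rate).astype(int).tolist()
    presence = pd.DataFrame(data, index=hs.site_id.tolist())
    cohort.presence = presence
    return presence


def simulate_cohort(config: Optional[SimulationConfig] = None) -> SyntheticCohort:
    """Run all simulation stages and return the complete bundle."""
    cohort = simulate_genomes(config or SimulationConfig())
    emit_chains(cohort)
    plant_features(cohort)
    simulate_individual_presence(cohort)
    return cohort
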