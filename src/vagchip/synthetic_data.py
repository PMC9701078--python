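"""Synthetic ground-truth inputs for every pipeline stage.

Generates (i) multi-strain gene sets with shared core genes (~95% identity
across strains, so they fail the marker uniqueness rule) and strain-unique
random genes, (ii) shotgun reads at controlled strain ratios with uniform
substitution errors, optional low-quality tails and a labeled host-read
fraction from a decoy pool, (iii) tracer transfer experiments with a known
true permeability, and (iv) effluent/digest CFU tables. All generators are
deterministic under an explicit seed and carry their ground truth, so every
downstream estimator can be tested closed-loop with no external data.

The defaults mirror the chip study conditions: 150 bp reads, ~10^5 CFU
inocula for optimal consortia, 160 uL effluent collections, and a host-read
knob motivated by the ~97% human-read content of epithelial digest libraries
(host *removal* is upstream of this package; synthetic host reads simply
never match the markers and surface as the unassigned fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chip_assays import CfuRecord, PermeabilityInputs
from .strain_composition import (
    MarkerSelectionParams,
    QualityRead,
    StrainGeneSet,
    select_marker_genes,
)

__all__ = [
    "ConsortiumSpec",
    "simulate_strain_genes",
    "simulate_reads",
    "simulate_tracer_experiment",
    "simulate_cfu_tables",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ConsortiumSpec:
    """Parameters of a synthetic defined consortium and its sequencing run.

    ``mean_marker_depth_x`` sets the total bacterial read number so that the
    consortium-wide mean gene depth equals it (a strain with share r then
    sits at ``r * n_strains * mean_marker_depth_x`` for equal gene sets).
    ``host_fraction`` is the fraction of all reads drawn from a decoy host
    pool.
    """

    n_strains: int = 4
    n_core_genes: int = 6
    n_unique_genes: int = 8
    gene_length_bp: int = 600
    core_identity: float = 0.95
    true_ratios: tuple[float, ...] | None = None
    host_fraction: float = 0.0
    read_length_bp: int = 150
    mean_marker_depth_x: float = 60.0
    error_rate: float = 0.005
    low_quality_tail_fraction: float = 0.1
    low_quality_tail_bp: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_unique_genes < 1:
            raise ValueError("need >= 1 strain with >= 1 unique gene")
        if self.gene_length_bp < self.read_length_bp:
            raise ValueError("genes must be at least one read long")
        if not (0.0 <= self.host_fraction < 1.0):
            raise ValueError("host_fraction must be in [0, 1)")
        if self.mean_marker_depth_x <= 0:
            raise ValueError("mean_marker_depth_x must be > 0")
        if self.true_ratios is not None:
            r = np.asarray(self.true_ratios)
            if len(r) != self.n_strains:
                raise ValueError("true_ratios length must equal n_strains")
            if np.any(r < 0) or not np.isclose(r.sum(), 1.0):
                raise ValueError("true_ratios must be >= 0 and sum to 1")

    @property
    def ratios(self) -> np.ndarray:
        if self.true_ratios is None:
            return np.full(self.n_strains, 1.0 / self.n_strains)
        return np.asarray(self.true_ratios, dtype=float)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with a different base
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(codes + shift) % 4]
    return "".join(arr)


def simulate_strain_genes(spec: ConsortiumSpec) -> list[StrainGeneSet]:
    """Generate gene sets for each strain of a consortium.

    Core genes are copied across strains with per-base substitution down to
    ``core_identity`` (they cross-match at the 70%/70% rule and are excluded
    from markers); unique genes are independent random sequences. Marker
    selection is run on the result to verify that exactly the unique genes
    survive; a violation (possible only for pathological parameter choices)
    raises rather than returning an unlabeled truth.
    """
    rng = np.random.default_rng(spec.seed)
    core_templates = [_random_seq(rng, spec.gene_length_bp)
                      for _ in range(spec.n_core_genes)]
    strains = []
    for s in range(spec.n_strains):
        sid = f"strain_{s + 1:02d}"
        genes = []
        for c, template in enumerate(core_templates):
            genes.append((f"core_{c + 1:03d}",
                          _mutate(rng, template, 1.0 - spec.core_identity)))
        for u in range(spec.n_unique_genes):
            genes.append((f"{sid}_unique_{u + 1:03d}",
                          _random_seq(rng, spec.gene_length_bp)))
        strains.append(StrainGeneSet(strain_id=sid, genes=tuple(genes)))
    markers = select_marker_genes(strains, MarkerSelectionParams())
    for ms in markers:
        got = {gid for gid, _ in ms.markers}
        want = {gid for gid, _ in
                dict(strains[int(ms.strain_id.split("_")[1]) - 1].genes).items()
                if "unique" in gid}
        if got != want:
            raise ValueError(
                f"generated genes violate the marker construction for "
                f"{ms.strain_id}: expected {sorted(want)}, got {sorted(got)}")
    return strains


@dataclass
class ReadSimResult:
    reads: list[QualityRead]
    truth: pd.DataFrame            # read_id, origin, gene_id
    n_bacterial: int
    n_host: int


def simulate_reads(gene_sets: list[StrainGeneSet], spec: ConsortiumSpec,
                   ) -> ReadSimResult:
    """Draw shotgun reads from a consortium plus a decoy host pool.

    Strains are sampled per ``true_ratios``, genes per strain uniformly by
    length, positions uniformly along the gene, strand at random;
    substitution errors at ``error_rate``; base quality Q35 with an optional
    low-quality (Q10) tail on a fraction of reads to exercise trimming. Host
    reads come from 20 independent random 2-kb decoy contigs. Ground truth is
    returned as a tidy table (origin = strain id or "host").
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = spec.read_length_bp
    total_bp = sum(sum(len(s) for _, s in gs.genes) for gs in gene_sets)
    n_bact = int(round(spec.mean_marker_depth_x * total_bp / L))
    n_host = (int(round(n_bact * spec.host_fraction
                        / (1.0 - spec.host_fraction)))
              if spec.host_fraction > 0 else 0)
    host_pool = [_random_seq(rng, 2000) for _ in range(20)]

    strain_of_read = rng.choice(len(gene_sets), size=n_bact, p=spec.ratios)
    reads: list[QualityRead] = []
    truth_rows = []
    q_hi, q_lo = 35, 10

    def make_read(rid: str, template: str, origin: str, gene_id: str) -> None:
        start = int(rng.integers(0, len(template) - L + 1))
        seq = template[start:start + L]
        if spec.error_rate > 0:
            seq = _mutate(rng, seq, spec.error_rate)
        if rng.random() < 0.5:
            from .strain_composition import reverse_complement
            seq = reverse_complement(seq)
        quals = [q_hi] * L
        if (spec.low_quality_tail_fraction > 0
                and rng.random() < spec.low_quality_tail_fraction):
            quals[-spec.low_quality_tail_bp:] = (
                [q_lo] * spec.low_quality_tail_bp)
        reads.append(QualityRead(rid, seq, tuple(quals)))
        truth_rows.append((rid, origin, gene_id))

    for i, s in enumerate(strain_of_read):
        gs = gene_sets[s]
        lengths = np.array([len(seq) for _, seq in gs.genes], dtype=float)
        gi = int(rng.choice(len(gs.genes), p=lengths / lengths.sum()))
        gid, gseq = gs.genes[gi]
        make_read(f"read_{i:07d}", gseq, gs.strain_id, gid)
    for i in range(n_host):
        contig = host_pool[int(rng.integers(0, len(host_pool)))]
        make_read(f"host_{i:07d}", contig, "host", "")

    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin", "gene_id"])
    return ReadSimResult(reads=reads, truth=truth, n_bacterial=n_bact,
                         n_host=n_host)


def simulate_tracer_experiment(true_Papp_cm_s: float, area_cm2: float = 0.167,
                               V_r_ml: float = 0.16, V_d_ml: float = 0.16,
                               time_s: float = 14400.0,
                               C_d_in: float = 50.0) -> PermeabilityInputs:
    """Forward two-compartment tracer transfer with a known permeability.

    The apparent-permeability estimator normalizes the receiver flux by the
    volume-weighted mean donor concentration over the collection window,
    which for a mass-conserving pair of effluents equals the pooled
    concentration ``C_eq = C_d_in V_d / (V_r + V_d)``. The forward model
    therefore defines ``true_Papp`` against that same driving concentration:
    the receiver fills toward the pooled equilibrium,

        C_r(t) = C_eq * (1 - exp(-P A t / V_r)),

    with the dosing-effluent concentration fixed by mass conservation
    ``C_r V_r + C_d_out V_d = C_d_in V_d``. The estimator then recovers
    ``P * (1 - exp(-x)) / x`` with ``x = P A t / V_r``, i.e. the true value
    to first order in the transferred fraction. Defaults match the bench
    setup: 16.7 mm x 1 mm membrane window, 160 uL effluents, 4 h collection,
    50 ug/mL Cascade Blue dosing.
    """
    if true_Papp_cm_s < 0:
        raise ValueError("true permeability must be >= 0")
    C_eq = C_d_in * V_d_ml / (V_r_ml + V_d_ml)
    C_r = C_eq * (1.0 - np.exp(-true_Papp_cm_s * area_cm2 * time_s / V_r_ml))
    C_d_out = (C_d_in * V_d_ml - C_r * V_r_ml) / V_d_ml
    return PermeabilityInputs(V_r_ml=V_r_ml, V_d_ml=V_d_ml, area_cm2=area_cm2,
                              time_s=time_s, C_r=float(C_r),
                              C_d_out=float(C_d_out))


@dataclass
class CfuSimResult:
    records: list[CfuRecord]
    truth: dict = field(default_factory=dict)


def simulate_cfu_tables(growth_rate_per_h: float = 0.05,
                        adherent_fraction: float = 0.2,
                        seed: int = 0,
                        inoculum_cfu: float = 1e5,
                        noise_sigma: float = 0.3,
                        effluent_volume_ml: float = 0.16,
                        digest_volume_ml: float = 0.2,
                        inoculum_volume_ml: float = 0.035
                        ) -> CfuSimResult:
    """Effluent/digest CFU records around an exponential-growth trajectory.

    Total population N(t) = inoculum * exp(g t); a fixed ``adherent_fraction``
    stays on the epithelium (recovered in the 72-h digest), the rest is
    collected in the effluents at 24/48/72 h. Multiplicative lognormal noise
    of width ``noise_sigma`` (natural-log scale) perturbs each plating count;
    with zero noise and zero growth the digest/inoculum ratio is exactly the
    adherent fraction. Defaults: ~10^5 CFU in 35 uL inoculum, 160 uL effluent
    collections.
    """
    if growth_rate_per_h < 0 or not (0.0 <= adherent_fraction <= 1.0):
        raise ValueError("invalid growth rate or adherent fraction")
    rng = np.random.default_rng(seed)

    def noisy(x: float) -> float:
        return x * float(np.exp(rng.normal(0.0, noise_sigma))) \
            if noise_sigma > 0 else x

    records = [CfuRecord("T0", "inoculum", inoculum_cfu / inoculum_volume_ml,
                         inoculum_volume_ml)]
    for t in (24.0, 48.0, 72.0):
        n_t = inoculum_cfu * np.exp(growth_rate_per_h * t)
        effluent_cfu = noisy((1.0 - adherent_fraction) * n_t)
        records.append(CfuRecord(t, "effluent",
                                 effluent_cfu / effluent_volume_ml,
                                 effluent_volume_ml))
    n_72 = inoculum_cfu * np.exp(growth_rate_per_h * 72.0)
    digest_cfu = noisy(adherent_fraction * n_72)
    records.append(CfuRecord(72.0, "digest", digest_cfu / digest_volume_ml,
                             digest_volume_ml))
    truth = {"inoculum_cfu": inoculum_cfu,
             "adherent_fraction": adherent_fraction,
             "growth_rate_per_h": growth_rate_per_h}
    return CfuSimResult(records=records, truth=truth)
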