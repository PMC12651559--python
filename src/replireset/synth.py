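"""Synthetic experiment generators with known ground truth.

Every input class the analysis modules consume can be generated here under
a controlled truth record, so each pipeline stage is verifiable at desk
scale:

* pooled CRISPRi screen count tables (negative-binomial guide counts with
  gene-level fitness effects across an outgrowth),
* Luria-Delbruck fluctuation-assay mutant-count vectors,
* multifork replication run-out populations (per-cell fork configurations,
  stall / rear-end / degradation events, per-locus copy number),
* DAPI DNA-content intensity samples,
* stranded DNA-end (END-seq-like) coverage tracks.

All generators take an explicit integer seed; no global RNG state is used.

Replication model
-----------------
Cells in steady exponential growth carry ``generations_overlap + 1``
synchronous replication rounds; a cell of age ``a`` (density
``2 ln2 * 2^-a`` on [0, 1)) has round ``r`` (0 = oldest) at arm fraction
``(a + G - r) / (G + 1)``, forks of a pair advancing symmetrically on the
two replichores.  Run-out (initiation and division blocked, elongation
allowed) completes every round unless a configured stall locus intervenes:
the first fork to arrive there stalls with probability ``p_stall``; a
trailing (re-initiated) fork then rear-ends it with probability
``p_rearend_given_stall``, creating a one-ended DNA end.  Without Gam the
end is resected and the stalled round's nascent replicore is degraded from
the stall site through oriC to the sister fork — the round is reset and,
the blockage cleared, the remaining rounds finish.  An optional
``end_resection_bp`` lets the nuclease additionally chew one nascent layer
just beyond the stall site.  With Gam (degradation blocked) the collided
intermediate is frozen in place and persists as a non-integer chromosome
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coverage import CoverageTrack, track_from_binned
from .genome import GenomeMap
from .screen import CountMatrix, GuideLibrary

__all__ = [
    "ScreenTruth",
    "FluctuationTruth",
    "ReplicationTruth",
    "EndednessTruth",
    "simulate_screen_counts",
    "simulate_guide_reads",
    "write_fastq",
    "simulate_luria_delbruck",
    "simulate_replication_cells",
    "ReplicationPopulation",
    "render_runout_coverage",
    "render_dapi_intensities",
    "simulate_endseq_track",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Screen


@dataclass
class ScreenTruth:
    """Ground truth for a pooled CRISPRi fitness screen.

    ``fitness_effect`` maps condition name -> per-gene growth-rate deficit
    ``s`` (per doubling; 0 = neutral, -1 = fully dead when silenced).  A
    guide's effective deficit is ``e_i * s_g`` with efficacy ``e_i`` in
    [0, 1].  Over ``doublings`` d the expected abundance of guide i scales
    as ``2^(d * (1 + e_i * s_g))`` before renormalisation.
    """

    n_genes: int
    guides_per_gene: int
    baseline_abundance: np.ndarray
    guide_efficacy: np.ndarray
    fitness_effect: dict[str, np.ndarray]
    doublings: float = 10.0
    dispersion: float = 0.05
    library_size: int = 10_000_000

    def __post_init__(self):
        n = self.n_guides
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        self.guide_efficacy = np.asarray(self.guide_efficacy, dtype=float)
        if self.baseline_abundance.shape != (n,):
            raise ValueError("baseline_abundance must have one entry per guide")
        if not np.isclose(self.baseline_abundance.sum(), 1.0):
            raise ValueError("baseline abundances must sum to 1")
        if np.any((self.guide_efficacy < 0) | (self.guide_efficacy > 1)):
            raise ValueError("guide efficacies must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be non-negative")
        for cond, s in self.fitness_effect.items():
            s = np.asarray(s, dtype=float)
            if s.shape != (self.n_genes,):
                raise ValueError(f"fitness effects for {cond!r} must be per-gene")
            if np.any(s < -1) or not np.all(np.isfinite(s)):
                raise ValueError("fitness effects must be finite and >= -1")
            self.fitness_effect[cond] = s

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene

    @property
    def gene_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_genes), self.guides_per_gene)

    def library(self, seed: int = 0) -> GuideLibrary:
        """Deterministic random 20-nt guide library matching this truth."""
        rng = np.random.default_rng(seed)
        seqs = set()
        while len(seqs) < self.n_guides:
            draw = rng.integers(0, 4, size=(self.n_guides, 20))
            for row in draw:
                seqs.add("".join(_BASES[row]))
                if len(seqs) == self.n_guides:
                    break
        seqs = sorted(seqs)
        gene = self.gene_index
        return GuideLibrary(
            guide_ids=tuple(
                f"g{gene[i]:04d}_{i % self.guides_per_gene}" for i in range(self.n_guides)
            ),
            sequences=tuple(seqs),
            genes=tuple(f"gene{g:04d}" for g in gene),
        )

    @classmethod
    def random(
        cls,
        n_genes: int = 2000,
        guides_per_gene: int = 5,
        conditions: tuple[str, ...] = ("control", "experimental"),
        seed: int = 0,
        **kwargs,
    ) -> "ScreenTruth":
        """Neutral truth with lognormal library skew and realistic efficacies."""
        rng = np.random.default_rng(seed)
        n = n_genes * guides_per_gene
        base = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        base /= base.sum()
        eff = rng.beta(8.0, 2.0, size=n)
        effects = {c: np.zeros(n_genes) for c in conditions}
        return cls(
            n_genes=n_genes,
            guides_per_gene=guides_per_gene,
            baseline_abundance=base,
            guide_efficacy=eff,
            fitness_effect=effects,
            **kwargs,
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) via the gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_screen_counts(
    truth: ScreenTruth, n_replicates: int, seed: int
) -> CountMatrix:
    """Paired pre/post induction count matrices for every condition.

    Post-induction expected fractions are the baseline fractions scaled by
    ``2^(d (1 + e_i s_g))`` and renormalised; counts are NB-sampled at
    ``fraction x library_size`` with the truth's dispersion.  Deterministic
    under a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    gene = truth.gene_index
    sample_names, metas, columns = [], [], []
    for cond in sorted(truth.fitness_effect):
        s_guide = truth.guide_efficacy * truth.fitness_effect[cond][gene]
        exponent = truth.doublings * (1.0 + s_guide)
        if not np.all(np.isfinite(exponent)):
            raise ValueError("non-finite growth exponent")
        growth = np.exp2(exponent)
        frac_end = truth.baseline_abundance * growth
        frac_end /= frac_end.sum()
        for rep in range(1, n_replicates + 1):
            for timepoint, frac in (("pre", truth.baseline_abundance), ("post", frac_end)):
                sample_names.append(f"{cond}_{timepoint}_{rep}")
                metas.append(
                    {"condition": cond, "timepoint": timepoint, "replicate": str(rep)}
                )
                columns.append(
                    _nb_sample(rng, frac * truth.library_size, truth.dispersion)
                )
    lib = truth.library(seed=0)
    return CountMatrix(
        guide_ids=list(lib.guide_ids),
        genes=list(lib.genes),
        counts=np.column_stack(columns).astype(np.int64),
        samples=pd.DataFrame(metas, index=sample_names),
    )


def simulate_guide_reads(
    counts: np.ndarray,
    library: GuideLibrary,
    seed: int,
    n_unmatched: int = 0,
) -> list[str]:
    """Expand per-guide counts into a shuffled list of 20-nt reads.

    Optionally appends ``n_unmatched`` random non-library 20-mers.
    """
    rng = np.random.default_rng(seed)
    reads = [
        seq for seq, c in zip(library.sequences, counts) for _ in range(int(c))
    ]
    in_library = set(library.sequences)
    while n_unmatched > 0:
        seq = "".join(_BASES[rng.integers(0, 4, size=20)])
        if seq not in in_library:
            reads.append(seq)
            n_unmatched -= 1
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def write_fastq(reads, path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# Fluctuation assays


@dataclass
class FluctuationTruth:
    """Luria-Delbruck generative truth: m mutations/culture, rho = 1."""

    m: float = 1.0
    n_final: float = 1e9
    n_cultures: int = 10
    plating_fraction: float = 1.0
    mutant_fitness: float = 1.0

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if not (0 < self.plating_fraction <= 1):
            raise ValueError("plating fraction must be in (0, 1]")
        if self.mutant_fitness != 1.0:
            raise ValueError("only neutral mutant fitness (rho = 1) is modelled")


def simulate_luria_delbruck(
    truth: FluctuationTruth, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate mutant counts per culture under the Lea-Coulson model.

    Each culture receives Poisson(m) mutation events; an event founds a
    clone of final size ``floor(1/U)`` (U uniform on (0, 1]), the clone-size
    law P(K = k) = 1/(k (k+1)) implied by a mutation arising at a uniformly
    random point of exponential expansion.  Clone sizes are capped at the
    final population size and counts are binomially thinned by the plating
    fraction.  Returns ``(mutant_counts, titers)``.
    """
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(truth.m, size=truth.n_cultures)
    total = int(n_events.sum())
    counts = np.zeros(truth.n_cultures, dtype=np.int64)
    if total:
        u = rng.random(total)
        sizes = np.minimum(np.floor(1.0 / (1.0 - u)), truth.n_final).astype(np.int64)
        owner = np.repeat(np.arange(truth.n_cultures), n_events)
        np.add.at(counts, owner, sizes)
        counts = np.minimum(counts, int(truth.n_final))
    if truth.plating_fraction < 1.0:
        counts = rng.binomial(counts, truth.plating_fraction)
    titers = np.full(truth.n_cultures, float(truth.n_final))
    return counts, titers


# ---------------------------------------------------------------------------
# Replication run-out


@dataclass
class ReplicationTruth:
    """Truth for a multifork replication / run-out population.

    ``sister_escape`` controls the fate of the stalled round's sister
    replisome when the round is reset: by default degradation captures the
    sister at the oriC-equidistant point and the whole nascent replicore is
    lost (the cell reverts exactly one replication round); with
    ``sister_escape=True`` the resolved sister replisome finishes its arm,
    leaving the distal nascent fragment beyond the capture point in place.
    """

    genome: GenomeMap
    generations_overlap: int = 0
    stall_locus: int | None = None
    p_stall: float = 0.0
    p_rearend_given_stall: float = 0.0
    gam_mode: bool = False
    end_resection_bp: int = 0
    sister_escape: bool = False

    def __post_init__(self):
        if self.generations_overlap < 0:
            raise ValueError("generations_overlap must be >= 0")
        for p in (self.p_stall, self.p_rearend_given_stall):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.stall_locus is not None and not (
            0 <= self.stall_locus < self.genome.length
        ):
            raise ValueError("stall locus outside genome")
        if self.end_resection_bp < 0:
            raise ValueError("end resection must be non-negative")

    @property
    def stall_replichore(self) -> str | None:
        if self.stall_locus is None:
            return None
        return self.genome.replichore(self.stall_locus)

    @property
    def stall_arm_fraction(self) -> float | None:
        if self.stall_locus is None:
            return None
        arm = self.genome.arm_length(self.stall_replichore)
        return self.genome.origin_distance(self.stall_locus) / arm

    @property
    def sister_fork_locus(self) -> int | None:
        """Where degradation halts on the other replichore (mirror of stall)."""
        if self.stall_locus is None:
            return None
        return self.genome.mirror_locus(self.stall_locus)


# cell fate codes
FATE_NONE = 0  # no round met the stall locus in the window
FATE_PASS = 1  # leading fork bypassed the block
FATE_FROZEN = 2  # stalled (or Gam-stabilised) intermediate persists
FATE_RESET = 3  # rear-ended, nascent replicore degraded


class ReplicationPopulation:
    """Per-cell replication state after simulation.

    Each round's nascent DNA on an arm is the half-open arm-fraction
    interval ``[lo, hi)``; ``lo`` is 0 except for a reset round whose
    resolved sister replisome escaped the degradation (leaving only the
    fragment beyond the capture point).  Fully degraded rounds are NaN.
    ``fate`` holds the per-cell event code.
    """

    def __init__(self, truth: ReplicationTruth, left, right, fate,
                 left_lo=None, right_lo=None):
        self.truth = truth
        self.genome = truth.genome
        self.left = np.asarray(left, dtype=float)
        self.right = np.asarray(right, dtype=float)
        self.left_lo = (
            np.zeros_like(self.left) if left_lo is None else np.asarray(left_lo, float)
        )
        self.right_lo = (
            np.zeros_like(self.right) if right_lo is None else np.asarray(right_lo, float)
        )
        self.fate = np.asarray(fate, dtype=np.int8)

    @property
    def n_cells(self) -> int:
        return self.left.shape[0]

    def _bin_geometry(self, bin_width: int):
        genome = self.genome
        n = int(np.ceil(genome.length / bin_width))
        starts = np.arange(n) * bin_width
        ends = np.minimum(starts + bin_width, genome.length)
        centres = starts + (ends - starts) // 2
        is_right = np.array([genome.replichore(int(c)) == "right" for c in centres])
        dist = np.array([genome.origin_distance(int(c)) for c in centres], dtype=float)
        rel = np.where(
            is_right,
            dist / genome.arm_length("right"),
            dist / genome.arm_length("left"),
        )
        widths = (ends - starts).astype(float)
        return is_right, rel, widths

    def _resection_span(self) -> tuple[str, float, float] | None:
        truth = self.truth
        if truth.stall_locus is None or truth.end_resection_bp <= 0:
            return None
        arm = truth.stall_replichore
        x0 = truth.stall_arm_fraction
        x1 = min(x0 + truth.end_resection_bp / self.genome.arm_length(arm), 1.0)
        return arm, x0, x1

    def copy_number_profile(self, bin_width: int = 1000) -> np.ndarray:
        """Population mean per-locus copy number on a bin grid."""
        is_right, rel, widths = self._bin_geometry(bin_width)
        rel_r = rel[is_right]
        rel_l = rel[~is_right]
        total = np.zeros(len(rel))
        resect = self._resection_span()
        acc_r = np.zeros(len(rel_r))
        acc_l = np.zeros(len(rel_l))
        R = self.left.shape[1]
        for c in range(self.n_cells):
            prof = {}
            for key, hi_all, lo_all, rel_arm in (
                ("right", self.right[c], self.right_lo[c], rel_r),
                ("left", self.left[c], self.left_lo[c], rel_l),
            ):
                count = np.zeros(len(rel_arm), dtype=np.int64)
                for r in range(R):
                    hi = hi_all[r]
                    if np.isnan(hi):
                        continue
                    lo = lo_all[r]
                    count += (rel_arm >= lo) & (rel_arm < hi)
                # copies double with every round whose nascent spans the locus
                prof[key] = np.exp2(count).astype(float)
            if resect is not None and self.fate[c] == FATE_RESET:
                arm, x0, x1 = resect
                rel_arm = rel_r if arm == "right" else rel_l
                p = prof[arm]
                sel = (rel_arm >= x0) & (rel_arm < x1) & (p >= 2)
                p[sel] -= 1.0  # one nascent layer resected; parental kept
            acc_r += prof["right"]
            acc_l += prof["left"]
        total[is_right] = acc_r
        total[~is_right] = acc_l
        return total / self.n_cells

    def chromosome_equivalents(self) -> np.ndarray:
        """Per-cell DNA content in chromosome equivalents (genome units)."""
        genome = self.genome
        w_r = genome.arm_length("right") / genome.length
        w_l = genome.arm_length("left") / genome.length
        eq = np.zeros(self.n_cells)
        resect = self._resection_span()
        R = self.left.shape[1]
        for c in range(self.n_cells):
            for hi_all, lo_all, w, arm in (
                (self.right[c], self.right_lo[c], w_r, "right"),
                (self.left[c], self.left_lo[c], w_l, "left"),
            ):
                intervals = [
                    (lo_all[r], hi_all[r])
                    for r in range(R)
                    if not np.isnan(hi_all[r]) and hi_all[r] > lo_all[r]
                ]
                edges = [p for iv in intervals for p in iv]
                if resect is not None and arm == resect[0]:
                    edges += [resect[1], resect[2]]
                pts = np.unique(np.r_[0.0, 1.0, edges])
                pts = pts[(pts >= 0.0) & (pts <= 1.0)]
                integral = 0.0
                for a, b in zip(pts[:-1], pts[1:]):
                    mid = 0.5 * (a + b)
                    n_cov = sum(1 for lo, hi in intervals if lo <= mid < hi)
                    copy = 2.0**n_cov
                    if (
                        resect is not None
                        and self.fate[c] == FATE_RESET
                        and arm == resect[0]
                        and resect[1] <= mid < resect[2]
                        and copy >= 2
                    ):
                        copy -= 1.0
                    integral += copy * (b - a)
                eq[c] += w * integral
        return eq


def simulate_replication_cells(
    truth: ReplicationTruth,
    n_cells: int,
    seed: int,
    stage: str = "runout",
    advance: float | None = None,
) -> ReplicationPopulation:
    """Draw a population of per-cell fork configurations.

    ``stage="exponential"`` returns the steady-state age-structured fork
    positions.  ``stage="runout"`` advances every fork by ``advance`` arm
    fractions (default: to completion), applying stall / rear-end /
    degradation bookkeeping at the configured stall locus (one stall
    opportunity per cell, taken by the first fork to arrive).
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if stage not in ("exponential", "runout"):
        raise ValueError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    G = truth.generations_overlap
    R = G + 1
    # steady-state exponential age structure: density 2 ln2 2^-a on [0, 1)
    a = -np.log2(1.0 - rng.random(n_cells) / 2.0)
    p0 = (a[:, None] + (G - np.arange(R))[None, :]) / R  # [cell, round], desc in r
    left = p0.copy()
    right = p0.copy()
    fate = np.full(n_cells, FATE_NONE, dtype=np.int8)
    if stage == "exponential":
        return ReplicationPopulation(truth, left, right, fate)

    delta = 2.0 if advance is None else float(advance)
    if delta < 0:
        raise ValueError("advance must be non-negative")

    if truth.stall_locus is None or truth.p_stall == 0.0:
        left = np.minimum(left + delta, 1.0)
        right = np.minimum(right + delta, 1.0)
        return ReplicationPopulation(truth, left, right, fate)

    x = truth.stall_arm_fraction
    stall_is_right = truth.stall_replichore == "right"
    # the oriC-equidistant capture point on the sister replichore, in that
    # arm's own fraction units
    d_bp = truth.genome.origin_distance(truth.stall_locus)
    other_arm_name = "left" if stall_is_right else "right"
    x_other = min(d_bp / truth.genome.arm_length(other_arm_name), 1.0)
    u_stall = rng.random(n_cells)
    u_re = rng.random(n_cells)
    left_lo = np.zeros_like(left)
    right_lo = np.zeros_like(right)

    for c in range(n_cells):
        p = p0[c]
        crossing = (p < x) & (p + delta >= x)
        if not np.any(crossing):
            left[c] = np.minimum(p + delta, 1.0)
            right[c] = np.minimum(p + delta, 1.0)
            continue
        owner = int(np.argmax(np.where(crossing, p, -np.inf)))
        stalled = u_stall[c] < truth.p_stall
        if not stalled:
            left[c] = np.minimum(p + delta, 1.0)
            right[c] = np.minimum(p + delta, 1.0)
            fate[c] = FATE_PASS
            continue
        rearended = u_re[c] < truth.p_rearend_given_stall
        if rearended and not truth.gam_mode:
            # replication reset: the stalled round's nascent replicore is
            # degraded from the DNA end at the stall site through oriC to
            # the sister fork (captured at the equidistant point); the
            # blockage clears and the remaining rounds finish
            new = np.minimum(p + delta, 1.0)
            new_l, new_r = new.copy(), new.copy()
            new_l[owner] = np.nan
            new_r[owner] = np.nan
            if truth.sister_escape:
                # resolution at the sister replisome lets it finish its
                # arm; the nascent fragment distal to the capture point
                # survives the degradation
                if stall_is_right:
                    new_l[owner] = 1.0
                    left_lo[c, owner] = x_other
                else:
                    new_r[owner] = 1.0
                    right_lo[c, owner] = x_other
            left[c], right[c] = new_l, new_r
            fate[c] = FATE_RESET
        else:
            # stalled (or Gam-stabilised) intermediate frozen at the block
            # as a coupled fork pair; trailing forks queue behind it on the
            # stalled arm
            new = np.minimum(p + delta, 1.0)
            stall_arm = new.copy()
            other_arm = new.copy()
            stall_arm[owner] = x
            other_arm[owner] = x_other
            for r in range(owner + 1, R):
                stall_arm[r] = min(stall_arm[r], x)
            if stall_is_right:
                right[c], left[c] = stall_arm, other_arm
            else:
                left[c], right[c] = stall_arm, other_arm
            fate[c] = FATE_FROZEN
    return ReplicationPopulation(truth, left, right, fate, left_lo, right_lo)


def render_runout_coverage(
    population: ReplicationPopulation,
    bin_width: int = 1000,
    depth: float = 100.0,
    seed: int = 0,
) -> CoverageTrack:
    """Poisson-sampled sequencing depth from a population's copy profile.

    Expected per-bin depth is ``depth`` reads per unit copy number times
    the population mean copy number at the bin; the track is unnormalised.
    """
    if population.n_cells == 0:
        raise ValueError("empty population")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    mean_copy = population.copy_number_profile(bin_width)
    values = rng.poisson(depth * mean_copy).astype(float)
    return track_from_binned(population.genome, values, bin_width=bin_width)


def render_dapi_intensities(
    population: ReplicationPopulation | np.ndarray,
    au_per_chromosome: float = 100.0,
    cv: float = 0.10,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell DAPI intensities: Normal(eq x AU, cv x mean), truncated at 0."""
    if cv <= 0:
        raise ValueError("cv must be positive")
    if isinstance(population, ReplicationPopulation):
        eq = population.chromosome_equivalents()
    else:
        eq = np.asarray(population, dtype=float)
    rng = np.random.default_rng(seed)
    mean = eq * au_per_chromosome
    return np.maximum(rng.normal(mean, cv * mean), 0.0)


# ---------------------------------------------------------------------------
# DNA-end (END-seq-like) tracks


@dataclass
class EndednessTruth:
    """Planted DNA-end sites with a known one-ended fraction."""

    end_sites: list[int] = field(default_factory=list)
    one_ended_fraction: float = 1.0
    depth: float = 100.0
    noise: float = 0.02

    def __post_init__(self):
        if not (0 <= self.one_ended_fraction <= 1):
            raise ValueError("one_ended_fraction must lie in [0, 1]")
        if self.depth <= 0 or self.noise < 0:
            raise ValueError("depth must be positive and noise non-negative")


def simulate_endseq_track(
    truth: EndednessTruth,
    genome: GenomeMap,
    seed: int,
    bin_width: int = 1000,
) -> CoverageTrack:
    """Stranded end-signal track from planted break sites.

    One-ended sites emit reads only on the strand facing away from oriC
    along their replichore (forward on the right replichore, reverse on the
    left); two-ended sites emit equally on both strands.  Poisson noise is
    added per bin and strand.
    """
    for site in truth.end_sites:
        if not (0 <= site < genome.length):
            raise ValueError(f"end site {site} outside genome")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(genome.length / bin_width))
    fwd = rng.poisson(truth.noise, size=n).astype(float)
    rev = rng.poisson(truth.noise, size=n).astype(float)
    for site in truth.end_sites:
        b = int(genome.wrap(site) // bin_width)
        away_is_fwd = genome.replichore(site) == "right"
        if rng.random() < truth.one_ended_fraction:
            reads = rng.poisson(truth.depth)
            if away_is_fwd:
                fwd[b] += reads
            else:
                rev[b] += reads
        else:
            fwd[b] += rng.poisson(truth.depth / 2.0)
            rev[b] += rng.poisson(truth.depth / 2.0)
    return track_from_binned(genome, fwd + rev, bin_width=bin_width, fwd=fwd, rev=rev)


# ---------------------------------------------------------------------------
# Truth sidecars


def _truth_to_dict(truth) -> dict:
    if isinstance(truth, ScreenTruth):
        return {
            "kind": "screen",
            "n_genes": truth.n_genes,
            "guides_per_gene": truth.guides_per_gene,
            "doublings": truth.doublings,
            "dispersion": truth.dispersion,
            "library_size": truth.library_size,
            "baseline_abundance": truth.baseline_abundance.tolist(),
            "guide_efficacy": truth.guide_efficacy.tolist(),
            "fitness_effect": {k: v.tolist() for k, v in truth.fitness_effect.items()},
        }
    if isinstance(truth, FluctuationTruth):
        return {
            "kind": "fluctuation",
            "m": truth.m,
            "n_final": truth.n_final,
            "n_cultures": truth.n_cultures,
            "plating_fraction": truth.plating_fraction,
            "mutant_fitness": truth.mutant_fitness,
        }
    if isinstance(truth, ReplicationTruth):
        return {
            "kind": "replication",
            "genome": {
                "length": truth.genome.length,
                "oric": truth.genome.oric,
                "terminus_window": list(truth.genome.terminus_window),
                "masked_intervals": [list(iv) for iv in truth.genome.masked_intervals],
                "loci": dict(truth.genome.loci),
            },
            "generations_overlap": truth.generations_overlap,
            "stall_locus": truth.stall_locus,
            "p_stall": truth.p_stall,
            "p_rearend_given_stall": truth.p_rearend_given_stall,
            "gam_mode": truth.gam_mode,
            "end_resection_bp": truth.end_resection_bp,
            "sister_escape": truth.sister_escape,
        }
    if isinstance(truth, EndednessTruth):
        return {
            "kind": "endedness",
            "end_sites": list(truth.end_sites),
            "one_ended_fraction": truth.one_ended_fraction,
            "depth": truth.depth,
            "noise": truth.noise,
        }
    raise TypeError(f"unknown truth type {type(truth)!r}")


def write_truth(truth, path) -> None:
    """Structured config-style sidecar for round-trip tests."""
    with open(path, "w") as fh:
        yaml.safe_dump(_truth_to_dict(truth), fh, sort_keys=True)


def read_truth(path):
    with open(path) as fh:
        data = yaml.safe_load(fh)
    kind = data.pop("kind")
    if kind == "screen":
        data["baseline_abundance"] = np.asarray(data["baseline_abundance"])
        data["guide_efficacy"] = np.asarray(data["guide_efficacy"])
        data["fitness_effect"] = {
            k: np.asarray(v) for k, v in data["fitness_effect"].items()
        }
        return ScreenTruth(**data)
    if kind == "fluctuation":
        return FluctuationTruth(**data)
    if kind == "replication":
        g = data.pop("genome")
        genome = GenomeMap(
            length=g["length"],
            oric=g["oric"],
            terminus_window=tuple(g["terminus_window"]),
            masked_intervals=[tuple(iv) for iv in g["masked_intervals"]],
            loci=g["loci"],
        )
        return ReplicationTruth(genome=genome, **data)
    if kind == "endedness":
        return EndednessTruth(**data)
    raise ValueError(f"unknown truth kind {kind!r}")
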