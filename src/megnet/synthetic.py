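"""Synthetic data with planted, recoverable structure.

Three generators make every downstream stage testable without any recorded
data:

* band-limited oscillatory ROI series with planted pairwise phase-lag
  coupling at known frequencies plus independent Gaussian noise — the
  oscillators are pure sinusoids with constant phase offsets, so the wPLI of
  a planted pair has an exact analytic limit of 1 in the noiseless case;
* deterministic toy graphs (star, complete, path, ring, planted rich club,
  two cliques) whose metric values are known in closed form or by exhaustive
  enumeration;
* synthetic cohorts of subjects at two timepoints whose scalar outcome
  (daily ethanol intake, g/kg) is linearly coupled — negatively, by default —
  to the minimum degree of a planted rich club, emulating a cohort in which
  baseline network differentiation predicts future drinking.

All randomness flows from user-supplied seeds through the package's
documented seed-splitting scheme, so identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seeds import child_rng
from .core import SourceSeriesSet
from .metrics import rewire_preserving_degree
from .network import Edge, FunctionalNetwork

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "CohortSubject",
    "default_roi_atlas",
    "generate_coupled_sources",
    "generate_toy_graph",
    "coupling_from_graph",
    "generate_cohort",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Planted pairwise couplings on top of independent channel noise.

    ``pairs`` entries are ``(roi_i, roi_j, frequency_Hz, phase_lag_rad,
    coupling_amplitude)``.  Each coupled pair receives a shared sinusoid at
    its frequency with the stated constant phase lag between the two
    channels, scaled by ``oscillator_amplitude * coupling_amplitude``; every
    channel additionally carries independent Gaussian noise of SD
    ``noise_sd``.  Uncoupled channel pairs share no common signal.
    """

    pairs: tuple = ()
    noise_sd: float = 1.0
    oscillator_amplitude: float = 1.0

    def __post_init__(self) -> None:
        seen = set()
        for i, j, f, lag, amp in self.pairs:
            if i == j:
                raise ValueError(f"coupling pair ({i}, {j}) couples an ROI to itself")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate coupling pair {key}")
            seen.add(key)
            if f <= 0:
                raise ValueError(f"coupling frequency must be positive, got {f}")
            if not (-np.pi < lag <= np.pi):
                raise ValueError(f"phase lag must lie in (-pi, pi], got {lag}")
            if amp < 0:
                raise ValueError("coupling amplitude must be non-negative")
        if self.noise_sd < 0 or self.oscillator_amplitude < 0:
            raise ValueError("noise_sd and oscillator_amplitude must be non-negative")


def default_roi_atlas() -> tuple[list[str], dict[str, str]]:
    """A 41-label ROI set over default-mode and reward structures.

    Returns ``(roi_labels, collapse_map)`` where the collapse map sends each
    ROI aspect (left/right, anterior/medial/posterior subdivisions) to its
    parent structure, as used when tabulating hub / rich-club membership at
    the structure level.  The labels are a synthetic stand-in atlas with the
    cardinality (41 ROIs) and structure list of a macaque default-mode +
    reward parcellation.
    """
    bilateral = {
        "anterior_cingulate": "Cingulate",
        "medial_orbitofrontal": "OrbitoFrontal",
        "lateral_orbitofrontal": "OrbitoFrontal",
        "anterior_principal_sulcus": "PrincipalSulcus",
        "posterior_principal_sulcus": "PrincipalSulcus",
        "nucleus_accumbens": "Accumbens",
        "caudate_head": "Caudate",
        "caudate_body": "Caudate",
        "putamen_head": "Putamen",
        "parietal": "Parietal",
        "precuneus": "Precuneus",
        "lateral_amygdala": "Amygdala",
        "medial_amygdala": "Amygdala",
        "anterior_hippocampus": "Hippocampus",
        "medial_hippocampus": "Hippocampus",
        "posterior_hippocampus": "Hippocampus",
        "anterior_cerebellum": "Cerebellum",
        "posterior_cerebellum": "Cerebellum",
        "thalamus": "Thalamus",
        "anterior_insula": "Insula",
    }
    labels: list[str] = []
    collapse: dict[str, str] = {}
    for aspect, structure in bilateral.items():
        for side in ("L", "R"):
            lab = f"{aspect}_{side}"
            labels.append(lab)
            collapse[lab] = structure
    labels.append("vermis")
    collapse["vermis"] = "Cerebellum"
    assert len(labels) == 41
    return labels, collapse


def _roi_labels(n_rois: int, labels: Sequence[str] | None) -> list[str]:
    if labels is not None:
        if len(labels) != n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        return list(labels)
    return [f"roi{k:02d}" for k in range(n_rois)]


def generate_coupled_sources(
    spec: CouplingSpec,
    n_rois: int,
    duration_s: float,
    fs: float,
    seed: int,
    roi_labels: Sequence[str] | None = None,
    subject_id: str = "sim",
    timepoint: str = "baseline",
) -> SourceSeriesSet:
    """ROI series with the planted couplings of ``spec``.

    Each coupled pair (i, j) shares a sinusoid at its frequency: channel i
    carries ``sin(2*pi*f*t + theta)`` with a random (seeded) base phase
    theta, channel j the same sinusoid delayed by the pair's phase lag.
    All channels carry independent Gaussian noise.  Identical arguments
    produce bit-identical output.
    """
    labels = _roi_labels(n_rois, roi_labels)
    index = {lab: k for k, lab in enumerate(labels)}
    t_n = int(round(duration_s * fs))
    if t_n < 2 * fs:
        raise ValueError("duration must be at least 2 s")
    for _i, _j, f, _lag, _amp in spec.pairs:
        if f >= fs / 2:
            raise ValueError(
                f"coupling frequency {f} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
    rng = child_rng(seed, "sources", subject_id, timepoint)
    t = np.arange(t_n) / fs
    data = spec.noise_sd * rng.standard_normal((n_rois, t_n))
    for i, j, f, lag, amp in spec.pairs:
        ii = index[i] if isinstance(i, str) else int(i)
        jj = index[j] if isinstance(j, str) else int(j)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        a = spec.oscillator_amplitude * amp
        data[ii] += a * np.sin(2 * np.pi * f * t + theta)
        data[jj] += a * np.sin(2 * np.pi * f * t + theta - lag)
    return SourceSeriesSet(
        subject_id=subject_id, timepoint=timepoint, fs=fs, roi_labels=labels, data=data
    )


def _toy_edges(pairs, f_star: float, z_max: float) -> list[Edge]:
    out = []
    for i, j in pairs:
        a, b = sorted((i, j))
        out.append(Edge(i=a, j=b, f_star=f_star, z_max=z_max))
    return out


def generate_toy_graph(
    kind: str,
    n_nodes: int | None = None,
    club_size: int | None = None,
    clique_size: int | None = None,
    f_star: float = 10.0,
    z_max: float = 5.0,
) -> FunctionalNetwork:
    """Deterministic fixture graphs with known metric values.

    Kinds: ``star``, ``complete``, ``path``, ``ring``, ``planted_club``
    (a ``club_size``-clique whose nodes are the unique highest-degree nodes,
    periphery wired as a degree-2 ring), ``two_cliques`` (two
    ``clique_size``-cliques joined by a single bridge edge).
    """
    def labels(n):
        return [f"roi{k:02d}" for k in range(n)]

    if kind in ("star", "complete", "path", "ring"):
        if n_nodes is None or n_nodes < 3:
            raise ValueError(f"{kind} graph needs n_nodes >= 3")
        labs = labels(n_nodes)
        if kind == "star":
            pairs = [(labs[0], labs[k]) for k in range(1, n_nodes)]
        elif kind == "complete":
            pairs = [
                (labs[a], labs[b]) for a in range(n_nodes) for b in range(a + 1, n_nodes)
            ]
        elif kind == "path":
            pairs = [(labs[k], labs[k + 1]) for k in range(n_nodes - 1)]
        else:  # ring
            pairs = [(labs[k], labs[(k + 1) % n_nodes]) for k in range(n_nodes)]
        return FunctionalNetwork(labs, _toy_edges(pairs, f_star, z_max))
    if kind == "planted_club":
        if n_nodes is None or club_size is None:
            raise ValueError("planted_club needs n_nodes and club_size")
        if club_size > n_nodes:
            raise ValueError("club_size cannot exceed n_nodes")
        if club_size < 4:
            raise ValueError(
                "club_size must be >= 4 so club degree exceeds the degree-2 periphery"
            )
        if n_nodes - club_size < 3:
            raise ValueError("periphery needs at least 3 nodes to form a ring")
        labs = labels(n_nodes)
        club = labs[:club_size]
        periph = labs[club_size:]
        pairs = [(club[a], club[b]) for a in range(club_size) for b in range(a + 1, club_size)]
        pairs += [(periph[k], periph[(k + 1) % len(periph)]) for k in range(len(periph))]
        return FunctionalNetwork(labs, _toy_edges(pairs, f_star, z_max))
    if kind == "two_cliques":
        if clique_size is None or clique_size < 3:
            raise ValueError("two_cliques needs clique_size >= 3")
        n = 2 * clique_size
        labs = labels(n)
        pairs = []
        for off in (0, clique_size):
            block = labs[off : off + clique_size]
            pairs += [
                (block[a], block[b])
                for a in range(clique_size)
                for b in range(a + 1, clique_size)
            ]
        pairs.append((labs[0], labs[clique_size]))
        return FunctionalNetwork(labs, _toy_edges(pairs, f_star, z_max))
    raise ValueError(f"unknown toy graph kind: {kind!r}")


def coupling_from_graph(
    net: FunctionalNetwork,
    noise_sd: float,
    oscillator_amplitude: float = 1.0,
    f_lo: float = 3.0,
    f_step: float = 1.5,
    f_hi: float = 79.0,
    seed: int = 0,
) -> CouplingSpec:
    """Turn a graph into a coupling spec: one sinusoidal coupling per edge.

    Each edge is assigned its own frequency on the grid
    ``f_lo + f_step * {0, 1, ...}`` up to ``f_hi``.  The default 1.5 Hz
    spacing keeps distinct oscillators at least three 0.5 Hz analysis bins
    apart: an on-bin sinusoid under a Hann taper leaks exactly one bin to
    either side, so closer spacing would let two unrelated edges deposit
    constant-phase energy in a shared bin and manufacture a phantom
    connection between their endpoints.  Phase lags are drawn (seeded) away
    from 0 and pi so the imaginary cross-spectrum is well separated from
    zero.
    """
    n_slots = int(np.floor((f_hi - f_lo) / f_step)) + 1
    if len(net.edges) > n_slots:
        raise ValueError(
            f"{len(net.edges)} edges exceed the {n_slots} distinct frequency "
            f"slots in [{f_lo}, {f_hi}] Hz at {f_step} Hz spacing; frequency "
            "reuse would plant phantom couplings between unrelated edges"
        )
    rng = child_rng(seed, "coupling")
    pairs = []
    for k, e in enumerate(net.edges):
        f = f_lo + f_step * k
        lag = rng.choice([-1.0, 1.0]) * rng.uniform(0.3 * np.pi, 0.7 * np.pi)
        pairs.append((e.i, e.j, f, lag, 1.0))
    return CouplingSpec(
        pairs=tuple(pairs), noise_sd=noise_sd, oscillator_amplitude=oscillator_amplitude
    )


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic two-timepoint cohort with a planted outcome relationship.

    Per subject, a rich club of minimum degree ``planted_min_degrees[s]`` is
    planted as a clique of size ``planted_min_degrees[s] + 1`` over
    ``n_rois`` ROIs (periphery wired as a degree-2 ring), realized as phase-
    lag couplings, and the scalar outcome is

    ``outcome = intercept + slope * planted_min_degree + N(0, noise)``

    in g/kg per day.  The default slope is negative: more differentiated
    baseline clubs predict lower future intake.
    """

    n_subjects: int = 6
    n_rois: int = 30
    ring_size: int = 12
    planted_min_degrees: tuple[int, ...] | None = None
    outcome_intercept: float = 4.7
    outcome_slope: float = -0.35
    outcome_noise_sd: float = 0.15
    noise_sd: float = 0.35
    oscillator_amplitude: float = 1.0
    duration_s: float = 60.0
    fs: float = 200.0
    seed: int = 0

    def degrees(self) -> tuple[int, ...]:
        if self.planted_min_degrees is not None:
            return tuple(self.planted_min_degrees)
        return tuple(3 + (k % 6) for k in range(self.n_subjects))

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects")
        degs = self.degrees()
        if len(degs) != self.n_subjects:
            raise ValueError("planted_min_degrees must have one entry per subject")
        for d in degs:
            if not 3 <= d < self.n_rois:
                raise ValueError(
                    f"planted minimum degree {d} must be in [3, n_rois): the club "
                    "clique must out-degree the degree-2 ring periphery"
                )
            if d + 1 + self.ring_size > self.n_rois:
                raise ValueError("club plus ring periphery must fit in n_rois")
            n_edges = (d + 1) * d // 2 + self.ring_size
            if n_edges > 51:  # distinct 1.5 Hz slots in [3, 79] Hz
                raise ValueError(
                    f"planted minimum degree {d} needs {n_edges} oscillators, "
                    "exceeding the 51 distinct coupling-frequency slots"
                )
        if self.ring_size < 3:
            raise ValueError("ring periphery needs at least 3 nodes")


@dataclass
class CohortSubject:
    """One synthetic subject: two scanned timepoints plus the drinking outcome."""

    subject_id: str
    baseline: SourceSeriesSet
    free_access: SourceSeriesSet
    outcome_g_per_kg: float
    planted_min_degree: int
    planted_graph: FunctionalNetwork = field(repr=False)


def _club_with_ring(n_rois: int, club_size: int, ring_size: int) -> FunctionalNetwork:
    """Club clique + a degree-2 ring over ``ring_size`` periphery nodes.

    Remaining ROIs are left uncoupled (pure noise channels), keeping the
    number of planted oscillators within the distinct-frequency budget while
    the club stays the unique highest-degree, fully interconnected subset.
    """
    labs = [f"roi{k:02d}" for k in range(n_rois)]
    club = labs[:club_size]
    ring = labs[club_size : club_size + ring_size]
    pairs = [(club[a], club[b]) for a in range(club_size) for b in range(a + 1, club_size)]
    pairs += [(ring[k], ring[(k + 1) % ring_size]) for k in range(ring_size)]
    return FunctionalNetwork(labs, _toy_edges(pairs, 10.0, 5.0))


def generate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Generate a cohort per :class:`CohortSpec`.

    The baseline coupling graph realizes the requested club exactly (club
    degree = planted minimum degree); the free-access graph is a
    degree-preserving rewiring of it, emulating membership reorganization
    without a change in degree sequence.
    """
    subjects = []
    degs = spec.degrees()
    for s in range(spec.n_subjects):
        sid = f"S{s + 1:02d}"
        pmd = degs[s]
        graph = _club_with_ring(spec.n_rois, club_size=pmd + 1, ring_size=spec.ring_size)
        rng = child_rng(spec.seed, "cohort", sid)
        coupling = coupling_from_graph(
            graph,
            noise_sd=spec.noise_sd,
            oscillator_amplitude=spec.oscillator_amplitude,
            seed=int(rng.integers(2**31)),
        )
        base = generate_coupled_sources(
            coupling,
            spec.n_rois,
            spec.duration_s,
            spec.fs,
            seed=int(rng.integers(2**31)),
            subject_id=sid,
            timepoint="baseline",
        )
        g2 = rewire_preserving_degree(graph, swaps_per_edge=2, seed=int(rng.integers(2**31)))
        net2 = FunctionalNetwork(
            node_labels=graph.node_labels,
            edges=[
                Edge(i=min(u, v), j=max(u, v), f_star=10.0, z_max=5.0)
                for u, v in g2.edges()
            ],
        )
        coupling2 = coupling_from_graph(
            net2,
            noise_sd=spec.noise_sd,
            oscillator_amplitude=spec.oscillator_amplitude,
            seed=int(rng.integers(2**31)),
        )
        free = generate_coupled_sources(
            coupling2,
            spec.n_rois,
            spec.duration_s,
            spec.fs,
            seed=int(rng.integers(2**31)),
            subject_id=sid,
            timepoint="free_access",
        )
        outcome = (
            spec.outcome_intercept
            + spec.outcome_slope * pmd
            + rng.normal(0.0, spec.outcome_noise_sd)
        )
        subjects.append(
            CohortSubject(
                subject_id=sid,
                baseline=base,
                free_access=free,
                outcome_g_per_kg=float(outcome),
                planted_min_degree=pmd,
                planted_graph=graph,
            )
        )
    return subjects
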