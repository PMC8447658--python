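"""Secondary survey analyses on top of the CSC ranking.

Three small tools that turn a ranking into curation decisions:

* :func:`expansion_ratio` — how much the accurately-reachable state count
  grows when a suggestion is realised.
* :func:`accurate_floating_components` — subnetworks held together by
  highly accurate lines that nevertheless have no accurate path to the
  root, found by comparing component partitions at two uncertainty
  thresholds.
* :func:`interval_scan` — the most productive wavenumber window of fixed
  length for an instrument that can only cover a limited spectral range.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .linelist import as_label
from .network import build_network, connected_components

__all__ = [
    "AccurateFloatingComponent",
    "IntervalScanResult",
    "expansion_ratio",
    "round_half_up",
    "accurate_floating_components",
    "is_sufficiently_large",
    "interval_scan",
    "SUFFICIENTLY_LARGE_RULES",
]

#: (minimum vertex count, uncertainty bound in cm^-1) alternatives under
#: which an accurate floating component counts as *sufficiently large*.
SUFFICIENTLY_LARGE_RULES = ((5, 5e-6), (30, 1e-5))


def expansion_ratio(h0_size: int, new_vertices: int) -> float:
    """Growth factor (|H0| + |Hi|) / |H0| of the accurate component."""
    if h0_size < 1:
        raise ValueError(f"h0_size must be >= 1, got {h0_size}")
    if new_vertices < 0:
        raise ValueError(f"new_vertices must be >= 0, got {new_vertices}")
    return (h0_size + new_vertices) / h0_size


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching how ratios are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AccurateFloatingComponent:
    """A subnetwork of accurate lines with no accurate path to the root.

    ``states`` are connected using only transitions with uncertainty below
    ``bound``; ``host_states`` is the full-network component the subgraph
    hides in (equal to ``states`` when the whole component floats).
    """

    states: frozenset
    transitions: tuple
    bound: float
    host_states: frozenset
    sufficiently_large: bool


def _max_component_under(transitions, bound: float) -> int:
    g = nx.Graph()
    g.add_edges_from(
        (t.upper, t.lower) for t in transitions if t.uncertainty < bound
    )
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def _sufficiently_large(transitions) -> bool:
    return any(
        _max_component_under(transitions, bound) >= n_min
        for n_min, bound in SUFFICIENTLY_LARGE_RULES
    )


def is_sufficiently_large(component: AccurateFloatingComponent) -> bool:
    """Apply the size rule: >=5 states under 5e-6 cm^-1 or >=30 under 1e-5.

    The rule re-examines the component's own transitions at both bounds,
    so a component assembled at a looser bound still qualifies only if a
    big enough sub-block meets one of the stricter bounds.
    """
    return _sufficiently_large(component.transitions)


def accurate_floating_components(
    all_transitions,
    accurate_threshold: float,
    root,
    full_threshold: float = 1.0,
) -> list[AccurateFloatingComponent]:
    """Find accurate floating components by a two-threshold comparison.

    Builds the network twice — once from transitions with uncertainty
    under ``accurate_threshold``, once under ``full_threshold`` (1 cm^-1
    by default, i.e. everything) — and reports every component of the
    accurate network that is disjoint from the root's accurate component,
    together with the full-network component hiding it.  At
    ``accurate_threshold = full_threshold`` this reduces to the plain
    floating components.
    """
    if not (accurate_threshold > 0 and full_threshold > 0):
        raise ValueError("thresholds must be positive")
    root = as_label(root)
    accurate = [t for t in all_transitions if t.uncertainty < accurate_threshold]
    full = [t for t in all_transitions if t.uncertainty < full_threshold]
    part_acc = connected_components(build_network(accurate, root))
    part_full = connected_components(build_network(full, root))

    out = []
    for comp in part_acc.components[1:]:
        trans = tuple(
            sorted(
                (t for t in accurate if t.upper in comp),
                key=lambda t: t.tag,
            )
        )
        rep = min(comp)
        host_idx = part_full.index_of(rep)
        host = part_full.components[host_idx] if host_idx is not None else comp
        out.append(
            AccurateFloatingComponent(
                states=comp,
                transitions=trans,
                bound=accurate_threshold,
                host_states=host,
                sufficiently_large=_sufficiently_large(trans),
            )
        )
    out.sort(key=lambda c: (-len(c.states), min(c.states)))
    return out


@dataclass
class IntervalScanResult:
    """Best fixed-length wavenumber window(s) for new measurements.

    ``A`` anchors the best window, ``B`` is the largest suggested
    wavenumber inside it (so any window containing [A, B] works; note
    B - A < L).  ``all_ties`` lists every (A, B) achieving ``best_T``;
    ``anchor_counts`` the component count of each candidate window;
    ``sparse_gaps`` consecutive suggested wavenumbers further apart
    than L — spectral regions contributing nothing.
    """

    L: float
    best_T: int
    A: float | None
    B: float | None
    all_ties: tuple
    anchor_counts: tuple
    sparse_gaps: tuple


def _covered(suggestion, lo: float, hi: float, complete_paths: bool) -> bool:
    in_window = lambda t: lo <= t.wavenumber <= hi
    if complete_paths:
        return any(
            all(any(in_window(t) for t in e.pool) for e in p.edges)
            for p in suggestion.paths
        )
    return any(in_window(t) for p in suggestion.paths for e in p.edges for t in e.pool)


def interval_scan(
    suggestions, L: float, complete_paths: bool = True
) -> IntervalScanResult:
    """Scan windows [t, t+L] anchored at each suggested wavenumber.

    A component counts as reachable within a window when some complete
    shortest path to it can be realised from pooled transitions whose
    wavenumbers all fall in the window (a partial path connects nothing).
    ``complete_paths=False`` switches to the looser per-edge counting,
    crediting a component as soon as any of its pooled candidates falls in
    the window.  Window endpoints are closed.
    """
    if not L > 0:
        raise ValueError(f"L must be positive, got {L!r}")
    wavenumbers = sorted(
        {
            t.wavenumber
            for s in suggestions
            for p in s.paths
            for e in p.edges
            for t in e.pool
        }
    )
    if not wavenumbers:
        return IntervalScanResult(L, 0, None, None, (), (), ())

    counts = []
    for a in wavenumbers:
        t_count = sum(1 for s in suggestions if _covered(s, a, a + L, complete_paths))
        counts.append((a, t_count))
    best = max(c for _, c in counts)
    ties = []
    for a, c in counts:
        if c != best:
            continue
        b = max(w for w in wavenumbers if a <= w <= a + L)
        if (a, b) not in ties:
            ties.append((a, b))
    gaps = tuple(
        (w1, w2)
        for w1, w2 in zip(wavenumbers, wavenumbers[1:])
        if w2 - w1 > L
    )
    a0, b0 = ties[0]
    return IntervalScanResult(L, best, a0, b0, tuple(ties), tuple(counts), gaps)
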