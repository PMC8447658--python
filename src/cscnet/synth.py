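"""Synthetic spectroscopic networks for testing and demonstration.

Two entry points:

* :func:`make_fig2_fixture` — a hand-built 21-state network with six
  internal components, one grey state and eight candidate lines.  Its
  contracted graph exercises every path scenario the ranking has to
  handle: direct single-edge connections, a choice between two parallel
  candidates, a two-edge route through another floating component, and a
  two-edge route through a grey state.
* :func:`generate` — seeded random networks with a requested component
  structure, used by the property-test suite.  Labels are synthetic
  integer-token tuples; wavenumbers are uniform draws (the ranking never
  reads wavenumbers except in interval scanning) and uncertainties come
  from a discrete mixture of accuracy levels, emulating how real line
  lists mix microwave, FT-IR and comb-referenced measurements.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .linelist import StateLabel, Transition

__all__ = ["SynthConfig", "make_fig2_fixture", "generate"]

# Uncertainty regimes of the hand-built fixture, separated by orders of
# magnitude so any threshold in (1e-6, 1e-2) splits it the same way.
FIXTURE_INTERNAL_UNC = 1e-6
FIXTURE_EXTERNAL_UNC = 1e-2
FIXTURE_THRESHOLD = 1e-3


def _lab(c, j) -> StateLabel:
    return (str(c), str(j))


def make_fig2_fixture():
    """Build the worked-example network.

    Returns ``(internal, external, root)``.  Internal components, in the
    figure's numbering: H0 = 3 states including the root, then H1..H5 of
    sizes 4, 3, 2, 4, 4 (component *labels* carry the figure number as
    their first token, e.g. state ``("3", "0")`` belongs to figure
    component H3).  External candidates realise exactly: H0-H1, H0-H2,
    H1-H2, H2-H3, H0-grey, grey-H4, and two parallel H0-H5 lines.

    Note the figure's numbering is not the size-ordered numbering the
    component partition uses; map between them through member states.
    """
    sizes = {0: 3, 1: 4, 2: 3, 3: 2, 4: 4, 5: 4}
    internal = []
    for c, n in sizes.items():
        for j in range(n - 1):
            internal.append(
                Transition(
                    wavenumber=10.0 + 10.0 * c + j,
                    uncertainty=FIXTURE_INTERNAL_UNC,
                    upper=_lab(c, j + 1),
                    lower=_lab(c, j),
                    tag=f"INT.{c}.{j}",
                )
            )
    grey = _lab("g", 0)
    ext_spec = [
        (_lab(1, 0), _lab(0, 1), 100.0),   # H0-H1
        (_lab(2, 0), _lab(0, 2), 150.0),   # H0-H2
        (_lab(2, 1), _lab(1, 1), 300.0),   # H1-H2
        (_lab(3, 0), _lab(2, 2), 450.0),   # H2-H3
        (grey, _lab(0, 1), 600.0),         # H0-grey
        (_lab(4, 0), grey, 750.0),         # grey-H4
        (_lab(5, 0), _lab(0, 0), 900.0),   # H0-H5, first candidate
        (_lab(5, 1), _lab(0, 1), 950.0),   # H0-H5, second candidate
    ]
    external = [
        Transition(w, FIXTURE_EXTERNAL_UNC, up, lo, f"EXT.{k}")
        for k, (up, lo, w) in enumerate(ext_spec, 1)
    ]
    return internal, external, _lab(0, 0)


@dataclass
class SynthConfig:
    """Parameters of a random spectroscopic network.

    ``edge_density`` is the probability of each extra within-component
    edge beyond the spanning tree that guarantees connectivity.
    ``grey_fraction`` is the probability that an external connection is
    routed through a fresh grey state (two candidate lines) instead of
    linking two components directly (one line).  The uncertainty mixture
    is a list of ``(level_cm-1, weight)`` pairs; each transition draws its
    uncertainty level independently.
    """

    n_components: int = 6
    size_range: tuple = (2, 6)
    edge_density: float = 0.3
    n_external: int = 10
    grey_fraction: float = 0.2
    wavenumber_range: tuple = (100.0, 5000.0)
    uncertainty_mixture: tuple = ((1e-6, 0.5), (1e-3, 0.5))
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.size_range
        if self.n_components < 1 or lo < 1 or hi < lo:
            raise ValueError("need n_components >= 1 and 1 <= size_min <= size_max")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 <= self.grey_fraction <= 1:
            raise ValueError("grey_fraction must be in [0, 1]")
        if self.n_external < 0:
            raise ValueError("n_external must be >= 0")
        wlo, whi = self.wavenumber_range
        if not 0 < wlo <= whi:
            raise ValueError("wavenumber_range must be positive and ordered")
        weights = [w for _, w in self.uncertainty_mixture]
        if not weights or abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
            raise ValueError("uncertainty mixture weights must sum to 1")
        if any(level <= 0 for level, _ in self.uncertainty_mixture):
            raise ValueError("uncertainty levels must be positive")


def generate(config: SynthConfig):
    """Generate a seeded random network; returns (internal, external, root).

    The root is state ``("0", "0")``.  Component membership is structural:
    the internal list connects each component (spanning tree plus random
    extra edges), the external list holds cross-component candidates,
    optionally routed through grey states.  All randomness comes from one
    ``random.Random(seed)`` stream, so output is reproducible byte for
    byte.
    """
    rng = random.Random(config.seed)
    lo, hi = config.size_range
    sizes = [rng.randint(lo, hi) for _ in range(config.n_components)]
    components = [
        [_lab(c, j) for j in range(n)] for c, n in enumerate(sizes)
    ]

    def draw_unc() -> float:
        return rng.choices(
            [level for level, _ in config.uncertainty_mixture],
            weights=[w for _, w in config.uncertainty_mixture],
        )[0]

    def draw_w() -> float:
        return round(rng.uniform(*config.wavenumber_range), 8)

    tag_counter = iter(range(1, 10**9))

    def make(upper, lower) -> Transition:
        return Transition(draw_w(), draw_unc(), upper, lower, f"SYN.{next(tag_counter)}")

    internal: list[Transition] = []
    for comp in components:
        for j in range(1, len(comp)):
            internal.append(make(comp[j], comp[rng.randrange(j)]))
        # extra edges beyond the spanning tree
        for a in range(len(comp)):
            for b in range(a + 1, len(comp)):
                if b != a + 1 and rng.random() < config.edge_density:
                    internal.append(make(comp[b], comp[a]))

    external: list[Transition] = []
    n_grey = 0
    while len(external) < config.n_external:
        budget = config.n_external - len(external)
        via_grey = (
            config.n_components >= 2
            and budget >= 2
            and rng.random() < config.grey_fraction
        )
        if config.n_components >= 2:
            c1, c2 = rng.sample(range(config.n_components), 2)
        else:
            c1 = c2 = 0
        a = rng.choice(components[c1])
        b = rng.choice(components[c2])
        if via_grey:
            g = _lab("g", n_grey)
            n_grey += 1
            external.append(make(a, g))
            external.append(make(g, b))
        elif a != b:
            external.append(make(a, b))
    return internal, external, _lab(0, 0)
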