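"""Reading and writing whitespace-delimited line-list ("segment") files.

A segment file stores one assigned transition per line::

    wavenumber  uncertainty  <upper-state labels>  <lower-state labels>  tag

Wavenumbers and uncertainties are in cm^-1; the uncertainty is the
half-width of a 95% confidence interval.  Each quantum state is labelled
by a fixed-arity tuple of tokens (quantum numbers, symmetry symbols,
counting indices); the arity differs between molecules and is supplied by
the caller.  Lines starting with ``#`` are comments.  By convention the
upper-state labels precede the lower-state labels; datasets using the
opposite order can set ``upper_first=False``.

Tags identify the literature source of a line (e.g. ``17UlBeGrBe.515``)
and must be unique within a file, because recommendation output refers to
candidate lines by tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StateLabel",
    "Transition",
    "ThresholdConfig",
    "LinelistError",
    "LinelistParseError",
    "as_label",
    "read_linelist",
    "write_linelist",
    "split_by_threshold",
    "add_magic_numbers",
    "write_csc_output",
    "MAGIC_TAG_PREFIX",
    "MAGIC_WAVENUMBER",
]

#: Type of a quantum-state label: an ordered tuple of label tokens.
StateLabel = tuple  # tuple[str, ...]

#: Reserved tag prefix for synthetic pseudo-root ("magic number") lines.
MAGIC_TAG_PREFIX = "MAGIC."

#: Placeholder wavenumber for pseudo-root lines.  Connectivity analysis
#: never reads the wavenumber of these lines, only their uncertainty.
MAGIC_WAVENUMBER = 1.0


class LinelistError(ValueError):
    """Invalid line-list content (validation failure)."""


class LinelistParseError(LinelistError):
    """A malformed line in a segment file; carries the 1-based line number."""

    def __init__(self, message: str, path: object = None, lineno: int | None = None):
        loc = f"{path}:{lineno}: " if lineno is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.lineno = lineno


def as_label(tokens: Iterable) -> StateLabel:
    """Normalise an iterable of label tokens to a canonical string tuple."""
    return tuple(str(t) for t in tokens)


@dataclass(frozen=True)
class Transition:
    """One measured or measurable line between two quantum states.

    Parameters
    ----------
    wavenumber : float
        Line position in cm^-1, strictly positive.
    uncertainty : float
        95% half-width in cm^-1, strictly positive.
    upper, lower : StateLabel
        Labels of the two connected quantum states; must differ.
    tag : str
        Non-empty source identifier, unique within a file.
    """

    wavenumber: float
    uncertainty: float
    upper: StateLabel
    lower: StateLabel
    tag: str

    def __post_init__(self):
        object.__setattr__(self, "upper", as_label(self.upper))
        object.__setattr__(self, "lower", as_label(self.lower))
        if not (self.wavenumber > 0 and math.isfinite(self.wavenumber)):
            raise LinelistError(f"wavenumber must be positive, got {self.wavenumber!r}")
        if not (self.uncertainty > 0 and math.isfinite(self.uncertainty)):
            raise LinelistError(f"uncertainty must be positive, got {self.uncertainty!r}")
        if self.upper == self.lower:
            raise LinelistError(f"upper and lower state labels coincide: {self.upper!r}")
        if not self.tag:
            raise LinelistError("tag must be a non-empty string")

    def record(self) -> str:
        """Render the transition in segment-file dialect (8 decimals)."""
        return " ".join(
            [f"{self.wavenumber:.8f}", f"{self.uncertainty:.8f}"]
            + list(self.upper)
            + list(self.lower)
            + [self.tag]
        )


@dataclass(frozen=True)
class ThresholdConfig:
    """Uncertainty threshold separating internal from external transitions.

    A transition with uncertainty *at least* ``threshold`` is external;
    strictly smaller means internal.
    """

    threshold: float
    mode: str = "split-one-file"  # or "two-files"

    def __post_init__(self):
        if not self.threshold > 0:
            raise LinelistError(f"threshold must be positive, got {self.threshold!r}")
        if self.mode not in ("split-one-file", "two-files"):
            raise LinelistError(f"unknown mode {self.mode!r}")


def parse_record(
    fields: Sequence[str],
    n_upper_cols: int,
    n_lower_cols: int,
    upper_first: bool = True,
) -> Transition:
    """Build a Transition from already-split record fields."""
    expected = 2 + n_upper_cols + n_lower_cols + 1
    if len(fields) != expected:
        raise LinelistError(
            f"expected {expected} fields "
            f"(2 numeric + {n_upper_cols}+{n_lower_cols} labels + tag), got {len(fields)}"
        )
    try:
        w = float(fields[0])
        u = float(fields[1])
    except ValueError as exc:
        raise LinelistError(f"non-numeric wavenumber/uncertainty: {exc}") from None
    if upper_first:
        upper = tuple(fields[2 : 2 + n_upper_cols])
        lower = tuple(fields[2 + n_upper_cols : 2 + n_upper_cols + n_lower_cols])
    else:
        lower = tuple(fields[2 : 2 + n_lower_cols])
        upper = tuple(fields[2 + n_lower_cols : 2 + n_lower_cols + n_upper_cols])
    return Transition(w, u, upper, lower, fields[-1])


def read_linelist(
    path,
    n_upper_cols: int,
    n_lower_cols: int,
    upper_first: bool = True,
) -> list[Transition]:
    """Read a segment file into a list of transitions, order preserved.

    Duplicate (upper, lower) state pairs are retained as distinct parallel
    transitions; duplicate tags are a hard error since downstream output
    refers to pooled candidate lines by tag.
    """
    path = Path(path)
    transitions: list[Transition] = []
    seen_tags: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                t = parse_record(line.split(), n_upper_cols, n_lower_cols, upper_first)
            except LinelistError as exc:
                raise LinelistParseError(str(exc), path, lineno) from None
            if t.tag in seen_tags:
                raise LinelistParseError(f"duplicate tag {t.tag!r}", path, lineno)
            seen_tags.add(t.tag)
            transitions.append(t)
    return transitions


def write_linelist(transitions: Iterable[Transition], path) -> None:
    """Write transitions in segment-file dialect, one record per line."""
    path = Path(path)
    with path.open("w") as fh:
        for t in transitions:
            fh.write(t.record() + "\n")


def split_by_threshold(
    transitions: Iterable[Transition], cfg: ThresholdConfig | float
) -> tuple[list[Transition], list[Transition]]:
    """Partition transitions into (internal, external) by uncertainty.

    The threshold is a lower bound for the external set: uncertainty
    exactly equal to the threshold is external.
    """
    thr = cfg.threshold if isinstance(cfg, ThresholdConfig) else float(cfg)
    if not thr > 0:
        raise LinelistError(f"threshold must be positive, got {thr!r}")
    internal = [t for t in transitions if t.uncertainty < thr]
    external = [t for t in transitions if t.uncertainty >= thr]
    return internal, external


def add_magic_numbers(
    transitions: Sequence[Transition],
    pseudo_edges: Iterable[tuple[StateLabel, StateLabel]],
    uncertainty: float,
    wavenumber: float = MAGIC_WAVENUMBER,
) -> list[Transition]:
    """Append synthetic pseudo-root lines ("magic numbers").

    Detached nuclear-spin or symmetry blocks have no physically allowed
    transition to the root; anchoring them requires artificial ultra-
    accurate lines whose wavenumber is a placeholder (only connectivity and
    uncertainty are ever used).  Added lines carry the reserved tag prefix
    ``MAGIC.`` followed by a running index.
    """
    if not uncertainty > 0:
        raise LinelistError(f"uncertainty must be positive, got {uncertainty!r}")
    out = list(transitions)
    existing = {t.tag for t in out}
    k = 1
    for a, b in pseudo_edges:
        a, b = as_label(a), as_label(b)
        if a == b:
            raise LinelistError(f"pseudo-edge endpoints coincide: {a!r}")
        while f"{MAGIC_TAG_PREFIX}{k}" in existing:
            k += 1
        tag = f"{MAGIC_TAG_PREFIX}{k}"
        existing.add(tag)
        out.append(Transition(wavenumber, uncertainty, a, b, tag))
    return out


CSC_OUTPUT_HEADER = "# path edge wavenumber uncertainty <upper labels> <lower labels> tag"


def write_csc_output(suggestions, path) -> None:
    """Write ranked suggestions in the standard recommendation dialect.

    One line per (path, edge, candidate transition): column 1 is a global
    path index (running over all paths of all suggestions, in rank order),
    column 2 the edge index within the path, columns 3+ the candidate
    transition record.  Lines of one path are contiguous.  An empty
    suggestion list yields a header-only file.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(CSC_OUTPUT_HEADER + "\n")
        path_idx = 0
        for sug in suggestions:
            for p in sug.paths:
                path_idx += 1
                for edge_idx, edge in enumerate(p.edges, 1):
                    for t in edge.pool:
                        fh.write(f"{path_idx} {edge_idx} {t.record()}\n")
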