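"""Drift-time vs drift-FWHM trendlines for cyclic ion-mobility peak smoothing.

A trendline fixes the assumed ion-mobility peak width (FWHM, in drift-time
bins) at the two ends of the 200-push gated acquisition window: ``fwhm_start``
at DT bin 0 and ``fwhm_end`` at DT bin 200.  Vendor-style peak detection uses
this line to set the kernel-smoothing width applied at each drift-time bin
before picking peaks.  In multipass cyclic separations the true DT-vs-FWHM
relationship becomes nonlinear through wrap-around, so several candidate
trendlines are applied iteratively and compared downstream.

Trendlines are written in the field's hyphenated notation, e.g. ``"11-13"``
meaning ``fwhm_start=11``, ``fwhm_end=13``; output folders use the underscore
form ``"11_13"``.  The single-pass (auto-calculated) dataset is always tagged
``"1_1"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DT_WINDOW",
    "SINGLE_PASS_TAG",
    "Trendline",
    "ProcessingPlan",
    "parse_trendline",
    "parse_trendline_list",
    "folder_tag",
    "fwhm_at",
    "fit_auto_trendline",
    "build_processing_plan",
]

#: Number of TOF pushes per gate pulse; DT bins run over [0, DT_WINDOW].
DT_WINDOW = 200.0

#: Folder tag reserved for single-pass data processed with the
#: auto-calculated trendline.
SINGLE_PASS_TAG = "1_1"

# accept ASCII hyphen, en-dash or minus between the two numbers
_TREND_RE = re.compile(
    r"^\s*([0-9]+(?:\.[0-9]+)?)\s*[-‐‑‒–—−]\s*"
    r"([0-9]+(?:\.[0-9]+)?)\s*$"
)


class TrendlineParseError(ValueError):
    """Raised when a trendline string cannot be interpreted."""


@dataclass(frozen=True)
class Trendline:
    """A linear DT-bin -> FWHM smoothing width model.

    Parameters
    ----------
    fwhm_start : float
        Drift FWHM (in DT bins) assumed at DT bin 0.  Must be > 0.
    fwhm_end : float
        Drift FWHM assumed at DT bin 200.  Must be > 0.
    """

    fwhm_start: float
    fwhm_end: float

    def __post_init__(self) -> None:
        for name in ("fwhm_start", "fwhm_end"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def fwhm_at(self, dt_bin: float) -> float:
        """FWHM at ``dt_bin``; see :func:`fwhm_at`."""
        return fwhm_at(self, dt_bin)

    @property
    def tag(self) -> str:
        """Folder tag, e.g. ``"11_13"``; see :func:`folder_tag`."""
        return folder_tag(self)

    def render(self) -> str:
        """Hyphenated input notation, e.g. ``"11-13"``."""
        return f"{_fmt(self.fwhm_start)}-{_fmt(self.fwhm_end)}"


def _fmt(x: float) -> str:
    """Render integers without a decimal point (11.0 -> "11")."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def parse_trendline(text: str) -> Trendline:
    """Parse one hyphen-separated trendline, e.g. ``"11-13"`` -> (11, 13).

    Accepts an ASCII hyphen or a typographic dash and surrounding whitespace.
    Raises :class:`TrendlineParseError` on malformed or non-positive input.
    """
    m = _TREND_RE.match(text)
    if m is None:
        raise TrendlineParseError(
            f"cannot parse trendline {text!r}; expected '<start>-<end>' like '11-13'"
        )
    start, end = float(m.group(1)), float(m.group(2))
    if start <= 0 or end <= 0:
        raise TrendlineParseError(
            f"trendline values must be > 0, got {start}-{end}"
        )
    return Trendline(start, end)


def parse_trendline_list(text: str) -> list[Trendline]:
    """Parse a comma-separated list of trendlines, e.g. ``"9-11, 21-23"``."""
    items = [piece for piece in text.split(",") if piece.strip()]
    if not items:
        raise TrendlineParseError("empty trendline list")
    return [parse_trendline(piece) for piece in items]


def folder_tag(t: Trendline) -> str:
    """Output-folder tag for a trendline: ``"start_end"`` (11,13 -> "11_13")."""
    return f"{_fmt(t.fwhm_start)}_{_fmt(t.fwhm_end)}"


def fwhm_at(t: Trendline, dt_bin: float) -> float:
    """Smoothing FWHM at a drift-time bin, by linear interpolation.

    The line passes through ``(0, fwhm_start)`` and ``(200, fwhm_end)``;
    bins outside [0, 200] are clamped to the nearest anchor value.
    """
    x = min(max(float(dt_bin), 0.0), DT_WINDOW)
    f = x / DT_WINDOW
    # convex combination: exact at both anchors
    return t.fwhm_start * (1.0 - f) + t.fwhm_end * f


class DegenerateFitError(ValueError):
    """Raised when an auto-trendline fit has fewer than two distinct DT bins."""


def fit_auto_trendline(
    points: list[tuple[float, float]], floor: float = 1.0
) -> Trendline:
    """Least-squares DT-vs-FWHM line, as the auto-calculated trendline.

    Fits ``fwhm = a + b * dt_bin`` by ordinary least squares over the
    supplied ``(dt_bin, fwhm)`` points and evaluates the line at DT bins 0
    and 200 to give the trendline anchors.  Anchors that come out at or
    below zero are clamped to ``floor`` (default 1.0) so the result is a
    valid smoothing width.

    Raises :class:`DegenerateFitError` with fewer than two distinct DT bins.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or len(np.unique(pts[:, 0])) < 2:
        raise DegenerateFitError(
            "auto-trendline fit needs >= 2 points with >= 2 distinct DT bins"
        )
    design = np.column_stack([np.ones(len(pts)), pts[:, 0]])
    (a, b), *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    start = max(a, floor) if a <= 0 else a
    end_raw = a + DT_WINDOW * b
    end = max(end_raw, floor) if end_raw <= 0 else end_raw
    return Trendline(start, end)


@dataclass(frozen=True)
class ProcessingPlan:
    """Iterative processing plan over user trendlines plus the single pass.

    ``multipass_trendlines`` hold the user-requested lines in input order
    with duplicates collapsed; ``output_layout`` maps each trendline
    (including the auto-calculated single-pass entry) to its folder tag.
    The single-pass folder tag is fixed to ``"1_1"``.
    """

    single_pass: Trendline
    multipass_trendlines: tuple[Trendline, ...]
    output_layout: dict[Trendline, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tags = list(self.output_layout.values())
        if len(tags) != len(set(tags)):
            raise ValueError("folder tags in a processing plan must be unique")
        if self.output_layout.get(self.single_pass) != SINGLE_PASS_TAG:
            raise ValueError(
                f"single-pass entry must be tagged {SINGLE_PASS_TAG!r}"
            )

    @property
    def tags(self) -> list[str]:
        """All folder tags, multipass first, then the single-pass tag."""
        return [folder_tag(t) for t in self.multipass_trendlines] + [SINGLE_PASS_TAG]


def build_processing_plan(
    trendline_texts: str,
    single_pass_points: list[tuple[float, float]] | None = None,
    single_pass: Trendline | None = None,
) -> ProcessingPlan:
    """Build the iterative plan from the user's trendline list string.

    ``single_pass_points`` (DT-bin, FWHM pairs from the single-pass data)
    are fitted into the auto-calculated trendline; alternatively an explicit
    ``single_pass`` trendline may be supplied.  With neither, a flat unit
    line stands in (the single-pass folder tag never depends on its values).
    """
    parsed = parse_trendline_list(trendline_texts)
    seen: dict[Trendline, None] = {}
    for t in parsed:
        seen.setdefault(t)
    multipass = tuple(seen)
    if single_pass is None:
        if single_pass_points is not None:
            single_pass = fit_auto_trendline(single_pass_points)
        else:
            single_pass = Trendline(1.0, 1.0)
    layout = {t: folder_tag(t) for t in multipass}
    if SINGLE_PASS_TAG in layout.values():
        raise ValueError(
            f"multipass trendline collides with the reserved single-pass tag "
            f"{SINGLE_PASS_TAG!r}"
        )
    layout[single_pass] = SINGLE_PASS_TAG
    return ProcessingPlan(single_pass, multipass, layout)
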