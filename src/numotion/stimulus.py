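"""Bar-layout sampling and first-/second-order motion rendering.

A trial shows N vertical bars on a field of random gray/white texels.  In
the first-order (luminance-defined) condition the bars are black; in the
second-order (contrast-defined) condition each bar is a region whose texels
have their polarity flipped (gray <-> white) frame by frame while the region
is displaced, producing "drift-balanced" motion with no luminance signature
in any single frame.

Frames are numpy uint8 arrays of shape (rows, cols) in texel units with
values in {BLACK, GRAY, WHITE}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import BLACK, GRAY, WHITE, DisplayGeometry, deg_to_texels

#: Columns x rows of the imaginary placement grid.
GRID_COLS: int = 17
GRID_ROWS: int = 12

#: The two admissible bar heights, degrees (equally likely).
BAR_HEIGHTS_DEG: tuple[float, float] = (2.08, 3.12)
BAR_WIDTH_DEG: float = 0.13

#: Minimum horizontal / vertical centre separations, degrees.
MIN_SEP_X_DEG: float = 1.84
MIN_SEP_Y_DEG: float = 0.98

#: Total lateral motion excursion, degrees (out and back).
MOTION_EXTENT_DEG: float = 1.84

#: Duration of the visible epoch, seconds.
VISIBLE_S: float = 0.133

DEFAULT_ATTEMPT_BUDGET: int = 10_000


class LayoutCapacityError(RuntimeError):
    """Raised when a layout cannot be placed on the grid."""


@dataclass(frozen=True)
class BarSpec:
    """One vertical bar: top-left anchor in degrees plus its extent."""

    x_deg: float
    y_deg: float
    width_deg: float
    height_deg: float
    col: int
    row: int

    def texel_rect(self, geometry: DisplayGeometry) -> tuple[int, int, int, int]:
        """(col0, row0, width, height) of the footprint, in texels."""
        x = int(round(self.x_deg * geometry.px_per_deg / geometry.texel_px))
        y = int(round(self.y_deg * geometry.px_per_deg / geometry.texel_px))
        w = deg_to_texels(self.width_deg, geometry)
        h = deg_to_texels(self.height_deg, geometry)
        return x, y, max(w, 1), max(h, 1)

    @property
    def center_deg(self) -> tuple[float, float]:
        return (self.x_deg + self.width_deg / 2, self.y_deg + self.height_deg / 2)


@dataclass(frozen=True)
class Layout:
    """A sampled set of bars for one trial at a stated numerosity."""

    numerosity: int
    bars: tuple[BarSpec, ...]

    def __post_init__(self) -> None:
        if len(self.bars) != self.numerosity:
            raise ValueError("len(bars) must equal numerosity")

    @property
    def mean_height_deg(self) -> float:
        return float(np.mean([b.height_deg for b in self.bars]))

    @property
    def grid_cells(self) -> tuple[tuple[int, int], ...]:
        return tuple((b.col, b.row) for b in self.bars)

    def to_json(self) -> str:
        return json.dumps({
            "numerosity": self.numerosity,
            "bars": [
                {"col": b.col, "row": b.row, "x_deg": b.x_deg, "y_deg": b.y_deg,
                 "w_deg": b.width_deg, "h_deg": b.height_deg}
                for b in self.bars
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Layout":
        obj = json.loads(text)
        bars = tuple(
            BarSpec(x_deg=b["x_deg"], y_deg=b["y_deg"], width_deg=b["w_deg"],
                    height_deg=b["h_deg"], col=b["col"], row=b["row"])
            for b in obj["bars"]
        )
        return cls(numerosity=obj["numerosity"], bars=bars)


@dataclass(frozen=True)
class MotionPath:
    """Per-frame horizontal offsets of the bars, in whole texels."""

    offsets_texels: tuple[int, ...]
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    @property
    def offsets_deg(self) -> tuple[float, ...]:
        return tuple(self.geometry.texels_to_deg(o) for o in self.offsets_texels)

    @property
    def n_frames(self) -> int:
        return len(self.offsets_texels)

    @property
    def max_offset_texels(self) -> int:
        return max(self.offsets_texels)


@dataclass
class FrameSequence:
    """Ordered luminance frames of one stimulus presentation.

    ``frames`` has shape (n_frames, rows, cols); ``duration_frames`` counts
    only the visible epoch (trailing background frames come after it).
    """

    frames: np.ndarray
    condition: str
    duration_frames: int

    def __post_init__(self) -> None:
        if self.condition not in ("first_order", "second_order"):
            raise ValueError(f"unknown condition: {self.condition}")
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")


# ---------------------------------------------------------------------------
# placement grid


def grid_cell_origin_texels(col: int, row: int,
                            geometry: DisplayGeometry) -> tuple[int, int]:
    """Top-left texel of a placement-grid cell.

    The grid pitch is the screen extent divided by the grid dimensions; cell
    origins are snapped to whole texels.
    """
    w_px, h_px = geometry.screen_px
    x_px = col * w_px / GRID_COLS
    y_px = row * h_px / GRID_ROWS
    return (int(round(x_px / geometry.texel_px)),
            int(round(y_px / geometry.texel_px)))


def _bar_from_cell(col: int, row: int, height_deg: float,
                   geometry: DisplayGeometry) -> BarSpec:
    x_t, y_t = grid_cell_origin_texels(col, row, geometry)
    return BarSpec(
        x_deg=geometry.texels_to_deg(x_t),
        y_deg=geometry.texels_to_deg(y_t),
        width_deg=BAR_WIDTH_DEG,
        height_deg=height_deg,
        col=col, row=row,
    )


def _bar_fits_on_screen(bar: BarSpec, geometry: DisplayGeometry,
                        motion_margin_texels: int) -> bool:
    cols, rows = geometry.screen_texels
    x, y, w, h = bar.texel_rect(geometry)
    return (x >= 0 and y >= 0 and y + h <= rows
            and x + w + motion_margin_texels <= cols)


def sample_layout(n: int, geometry: DisplayGeometry | None = None,
                  seed: int | np.random.Generator = 0,
                  attempt_budget: int = DEFAULT_ATTEMPT_BUDGET) -> Layout:
    """Sample a bar layout of numerosity ``n`` on the 17x12 placement grid.

    Each bar occupies a distinct grid cell (which guarantees the pairwise
    spacing constraints, see :func:`verify_layout`); heights are drawn
    i.i.d. uniform over the two height classes.  A 1.84-deg margin at the
    right screen edge is reserved for the rightward motion excursion.
    Placement is by rejection sampling: a draw whose bar would extend
    off-screen (a tall bar in the bottom grid row) is redrawn, within
    ``attempt_budget`` total attempts.

    Raises
    ------
    LayoutCapacityError
        If ``n`` exceeds the grid capacity or the budget is exhausted.
    """
    if n < 1:
        raise ValueError(f"numerosity must be >= 1, got {n}")
    geometry = geometry or DisplayGeometry()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_cells = GRID_COLS * GRID_ROWS
    if n > n_cells:
        raise LayoutCapacityError(
            f"cannot place {n} bars: the {GRID_COLS}x{GRID_ROWS} grid has "
            f"only {n_cells} cells"
        )
    margin = deg_to_texels(MOTION_EXTENT_DEG, geometry)
    free = list(range(n_cells))
    bars: list[BarSpec] = []
    attempts = 0
    while len(bars) < n:
        attempts += 1
        if attempts > attempt_budget:
            raise LayoutCapacityError(
                f"could not place {n} bars on the {GRID_COLS}x{GRID_ROWS} "
                f"grid within {attempt_budget} attempts"
            )
        idx = int(rng.integers(len(free)))
        cell = free[idx]
        col, row = cell % GRID_COLS, cell // GRID_COLS
        height = float(rng.choice(BAR_HEIGHTS_DEG))
        bar = _bar_from_cell(col, row, height, geometry)
        if not _bar_fits_on_screen(bar, geometry, margin):
            continue  # cell stays in the pool: a short bar may still fit
        free.pop(idx)
        bars.append(bar)
    return Layout(numerosity=n, bars=tuple(bars))


def verify_layout(layout: Layout, geometry: DisplayGeometry | None = None) -> None:
    """Brute-force pairwise check of all layout invariants.

    Independent of the sampler's bookkeeping: re-derives grid-cell
    uniqueness, on-screen footprints (with motion headroom) and, for every
    bar pair, the spacing disjunction ``|dx| >= 1.84 deg OR |dy| >= 0.98
    deg`` on centre coordinates.

    Raises ``ValueError`` on the first violated invariant.
    """
    geometry = geometry or DisplayGeometry()
    margin = deg_to_texels(MOTION_EXTENT_DEG, geometry)
    if len(layout.bars) != layout.numerosity:
        raise ValueError("bar count does not match numerosity")
    cells = set()
    for b in layout.bars:
        if b.height_deg not in BAR_HEIGHTS_DEG:
            raise ValueError(f"illegal bar height {b.height_deg}")
        if not (0 <= b.col < GRID_COLS and 0 <= b.row < GRID_ROWS):
            raise ValueError(f"grid cell ({b.col},{b.row}) outside grid")
        if (b.col, b.row) in cells:
            raise ValueError(f"duplicate grid cell ({b.col},{b.row})")
        cells.add((b.col, b.row))
        if not _bar_fits_on_screen(b, geometry, margin):
            raise ValueError(f"bar at cell ({b.col},{b.row}) off screen")
    for i in range(len(layout.bars)):
        for j in range(i + 1, len(layout.bars)):
            (xi, yi), (xj, yj) = (layout.bars[i].center_deg,
                                  layout.bars[j].center_deg)
            if abs(xi - xj) < MIN_SEP_X_DEG - 1e-9 and \
               abs(yi - yj) < MIN_SEP_Y_DEG - 1e-9:
                raise ValueError(
                    f"bars {i} and {j} violate the spacing constraint"
                )


# ---------------------------------------------------------------------------
# background and motion


def make_background(geometry: DisplayGeometry | None = None,
                    texture_seed: int = 0) -> np.ndarray:
    """A full-screen frame of i.i.d. gray/white texels (p = 1/2 each)."""
    geometry = geometry or DisplayGeometry()
    cols, rows = geometry.screen_texels
    rng = np.random.default_rng(texture_seed)
    white = rng.random((rows, cols)) < 0.5
    return np.where(white, WHITE, GRAY).astype(np.uint8)


def motion_path(geometry: DisplayGeometry | None = None) -> MotionPath:
    """The out-and-back lateral motion of the bars.

    The visible epoch is round(0.133 s x refresh) frames (10 at 75 Hz); the
    offsets rise to the 1.84-deg excursion over the first half and return to
    zero over the second, snapped to whole texels, with the rounding
    residual absorbed in the turnaround frames.
    """
    geometry = geometry or DisplayGeometry()
    n = int(round(VISIBLE_S * geometry.refresh_hz))
    peak = deg_to_texels(MOTION_EXTENT_DEG, geometry)
    half = n // 2
    up = [int(math.floor(peak * i / (half - 1) + 0.5)) for i in range(half)]
    down = list(reversed(up))
    offsets = up + down if n % 2 == 0 else up + [peak] + down
    return MotionPath(offsets_texels=tuple(offsets), geometry=geometry)


def _footprint_mask(layout: Layout, offset_texels: int,
                    geometry: DisplayGeometry) -> np.ndarray:
    cols, rows = geometry.screen_texels
    mask = np.zeros((rows, cols), dtype=bool)
    for bar in layout.bars:
        x, y, w, h = bar.texel_rect(geometry)
        x += offset_texels
        if x < 0 or x + w > cols or y < 0 or y + h > rows:
            raise ValueError(
                f"bar at cell ({bar.col},{bar.row}) pushed off screen at "
                f"offset {offset_texels} texels; the layout must leave "
                f"{MOTION_EXTENT_DEG} deg of rightward headroom"
            )
        mask[y:y + h, x:x + w] = True
    return mask


def render_first_order(layout: Layout, path: MotionPath,
                       background: np.ndarray,
                       geometry: DisplayGeometry | None = None,
                       trailing_frames: int = 0) -> FrameSequence:
    """Luminance-defined motion: bars drawn black over the static background.

    After the visible epoch, ``trailing_frames`` copies of the untouched
    background follow (the bars "disappear").
    """
    geometry = geometry or DisplayGeometry()
    frames = []
    for off in path.offsets_texels:
        frame = background.copy()
        frame[_footprint_mask(layout, off, geometry)] = BLACK
        frames.append(frame)
    frames.extend(background.copy() for _ in range(trailing_frames))
    return FrameSequence(frames=np.stack(frames), condition="first_order",
                         duration_frames=path.n_frames)


def render_second_order(layout: Layout, path: MotionPath,
                        background: np.ndarray | None = None,
                        geometry: DisplayGeometry | None = None,
                        texture_seed: int | None = None,
                        state_mode: str = "evolving",
                        trailing_frames: int = 0) -> FrameSequence:
    """Contrast-defined motion: polarity inversion within moving footprints.

    Each visible frame flips gray <-> white inside every bar's footprint at
    the current offset.  With ``state_mode="evolving"`` (the drift-balanced
    recipe: invert, displace, repeat) the texture state persists, so texels
    behind a departed bar may remain inverted; with ``state_mode="reset"``
    each frame inverts relative to the fixed background.  Either way no
    texel is ever black, and — because gray and white are exchangeable under
    the Bernoulli(1/2) texture — no single frame carries a luminance
    signature of the bars.
    """
    geometry = geometry or DisplayGeometry()
    if background is None:
        if texture_seed is None:
            raise ValueError("provide a background frame or a texture_seed")
        background = make_background(geometry, texture_seed)
    if state_mode not in ("evolving", "reset"):
        raise ValueError(f"unknown state_mode: {state_mode}")
    if np.any(background == BLACK):
        raise ValueError("second-order background must contain no black texels")
    state = background.copy()
    frames = []
    for off in path.offsets_texels:
        mask = _footprint_mask(layout, off, geometry)
        if state_mode == "reset":
            state = background.copy()
        # gray(128) <-> white(255): v -> 383 - v
        region = state[mask]
        state[mask] = (383 - region.astype(np.int16)).astype(np.uint8)
        frames.append(state.copy())
    frames.extend(background.copy() for _ in range(trailing_frames))
    return FrameSequence(frames=np.stack(frames), condition="second_order",
                         duration_frames=path.n_frames)


# ---------------------------------------------------------------------------
# export


def save_frames(seq: FrameSequence, out_dir: str | Path,
                prefix: str = "frame", fmt: str = "png",
                geometry: DisplayGeometry | None = None,
                gif: bool = False) -> list[Path]:
    """Write each frame as an 8-bit grayscale image, one file per frame.

    Frames are upsampled from texel to pixel resolution.  Optionally also
    writes an animated GIF of the whole sequence.
    """
    import imageio.v3 as iio

    geometry = geometry or DisplayGeometry()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    k = geometry.texel_px
    paths = []
    imgs = [np.kron(f, np.ones((k, k), dtype=np.uint8)) for f in seq.frames]
    for i, img in enumerate(imgs):
        p = out_dir / f"{prefix}_{i:03d}.{fmt}"
        iio.imwrite(p, img)
        paths.append(p)
    if gif:
        iio.imwrite(out_dir / f"{prefix}.gif", np.stack(imgs),
                    duration=1000.0 / geometry.refresh_hz, loop=0)
    return paths
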