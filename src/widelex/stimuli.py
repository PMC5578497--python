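"""Letter-string stimuli: lexicon handling, nonword construction,
rasterization, and discrete orientation/contrast cue extraction.

The visual front end deliberately stays at the level of edge-sensitive
measurements shared across primate and avian vision: each four-letter
string is rendered deterministically from a packaged bitmap font, the
raster is divided into four letter slots, each slot into a grid of cells,
and within every cell the image gradient is summarized by an orientation
histogram. A cue fires when the summed gradient magnitude in one
(cell, orientation-bin) exceeds a contrast threshold. The resulting cue
inventory is discrete, binary, and slot-tagged, which is all the learning
network downstream ever sees — there is no letter, bigram or word
representation anywhere in the code path.
"""

from __future__ import annotations

import csv
import enum
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .font_data import FONT_5X7, FONT_ID, GLYPH_COLS, GLYPH_ROWS

__all__ = [
    "Outcome",
    "Derivation",
    "ValidationError",
    "RejectionError",
    "WORD_LENGTH",
    "VOWELS",
    "CONSONANTS",
    "validate_letter_string",
    "Lexicon",
    "load_lexicon",
    "bundled_lexicon",
    "StimulusItem",
    "ngrams",
    "make_transposition_nonword",
    "make_substitution_nonword",
    "CueId",
    "FeatureConfig",
    "GlyphImage",
    "render",
    "extract_cues",
    "cue_cache",
    "write_cue_inventory",
    "write_cue_activations",
]

WORD_LENGTH = 4
VOWELS = frozenset("AEIOU")
CONSONANTS = frozenset("BCDFGHJKLMNPQRSTVWXYZ")

_LETTER_RE = re.compile(r"^[A-Z]{4}$")


class ValidationError(ValueError):
    """An input violates a structural contract (bad letter string, config...)."""


class RejectionError(ValueError):
    """A nonword could not be derived from the given word."""


class Outcome(enum.IntEnum):
    """The two response categories / lexicality labels of the task."""

    WORD = 0
    NONWORD = 1

    def __str__(self) -> str:  # CSV-friendly
        return self.name


class Derivation(enum.Enum):
    """How a stimulus item was obtained."""

    BASE = "BASE"
    TRANSPOSITION = "TRANSPOSITION"
    SUBSTITUTION = "SUBSTITUTION"
    POOL = "POOL"

    def __str__(self) -> str:
        return self.value


def validate_letter_string(text: str, *, where: str = "") -> str:
    """Validate a four-letter uppercase A-Z string and return it.

    Raises :class:`ValidationError` naming ``where`` on failure.
    """
    if not isinstance(text, str) or not _LETTER_RE.match(text):
        loc = f" ({where})" if where else ""
        raise ValidationError(
            f"expected a 4-letter uppercase A-Z string, got {text!r}{loc}"
        )
    return text


class Lexicon:
    """An ordered, duplicate-free collection of four-letter words."""

    def __init__(self, entries: Iterable[str]):
        seen: dict[str, None] = {}
        for i, raw in enumerate(entries):
            w = validate_letter_string(raw, where=f"entry {i + 1}")
            seen.setdefault(w, None)
        self._entries: tuple[str, ...] = tuple(seen)
        self._set = frozenset(self._entries)

    @property
    def entries(self) -> tuple[str, ...]:
        return self._entries

    def __contains__(self, w: object) -> bool:
        return w in self._set

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"Lexicon({len(self)} entries)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Lexicon) and self._entries == other._entries


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon from a plain-text file, one word per line.

    Tokens are uppercased and deduplicated preserving first occurrence;
    an invalid token raises :class:`ValidationError` naming its line.
    """
    words: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            token = token.upper()
            validate_letter_string(token, where=f"{path}:{lineno}")
            words.append(token)
    return Lexicon(words)


def bundled_lexicon() -> Lexicon:
    """The packaged reference lexicon of common four-letter English words."""
    return load_lexicon(Path(__file__).parent / "data" / "lexicon_4letter.txt")


@dataclass(frozen=True)
class StimulusItem:
    """A letter string plus its lexicality label and derivation provenance."""

    string: str
    lexicality: Outcome
    derivation: Derivation = Derivation.BASE
    base: str | None = None

    def __post_init__(self) -> None:
        validate_letter_string(self.string, where="StimulusItem.string")
        if self.base is not None:
            validate_letter_string(self.base, where="StimulusItem.base")
        if self.derivation is Derivation.BASE:
            if self.lexicality is not Outcome.WORD:
                raise ValidationError("BASE items must be labelled WORD")
        else:
            if self.lexicality is not Outcome.NONWORD:
                raise ValidationError(
                    f"{self.derivation} items must be labelled NONWORD"
                )
        if self.derivation in (Derivation.TRANSPOSITION, Derivation.SUBSTITUTION):
            # base may be None only for items re-read from a trial-log CSV,
            # whose dialect does not carry the source word
            if self.base is not None and self.base == self.string:
                raise ValidationError("derived nonword equals its base word")


def word_item(w: str) -> StimulusItem:
    return StimulusItem(w, Outcome.WORD, Derivation.BASE)


def pool_item(s: str) -> StimulusItem:
    return StimulusItem(s, Outcome.NONWORD, Derivation.POOL)


def ngrams(s: str, n: int) -> list[str]:
    """All contiguous length-``n`` substrings of ``s``, left to right.

    Positional: duplicates are kept (``ngrams("AAAA", 2)`` has three
    identical entries). ``n`` must be 2, 3 or 4.
    """
    validate_letter_string(s, where="ngrams")
    if n not in (2, 3, 4):
        raise ValidationError(f"n must be in {{2, 3, 4}}, got {n}")
    return [s[i : i + n] for i in range(len(s) - n + 1)]


def make_transposition_nonword(w: str, lex: Lexicon) -> StimulusItem:
    """Swap the two middle letters of ``w`` to produce a nonword.

    Rejects (``RejectionError``) when the middle letters are identical or
    the swapped form is itself a word of ``lex``.
    """
    validate_letter_string(w, where="make_transposition_nonword")
    if w not in lex:
        raise ValidationError(f"{w!r} is not in the lexicon")
    if w[1] == w[2]:
        raise RejectionError(f"{w}: middle letters identical, swap is identity")
    t = w[0] + w[2] + w[1] + w[3]
    if t in lex:
        raise RejectionError(f"{w}: transposed form {t} is itself a word")
    return StimulusItem(t, Outcome.NONWORD, Derivation.TRANSPOSITION, base=w)


def make_substitution_nonword(
    w: str, lex: Lexicon, rng: np.random.Generator, *, max_draws: int = 200
) -> StimulusItem:
    """Replace both middle letters of ``w`` by different same-class letters.

    Vowels are exchanged for vowels, consonants for consonants, so the
    result keeps the phonotactic skeleton of the base word while disturbing
    the same positions a transposition disturbs. Reproducible under a fixed
    ``rng`` state; raises :class:`RejectionError` if no legal nonword is
    found within ``max_draws`` draws.
    """
    validate_letter_string(w, where="make_substitution_nonword")
    if w not in lex:
        raise ValidationError(f"{w!r} is not in the lexicon")
    for _ in range(max_draws):
        subst = []
        for ch in w[1:3]:
            cls = VOWELS if ch in VOWELS else CONSONANTS
            choices = sorted(cls - {ch})
            subst.append(choices[int(rng.integers(len(choices)))])
        cand = w[0] + subst[0] + subst[1] + w[3]
        if cand not in lex:
            return StimulusItem(
                cand, Outcome.NONWORD, Derivation.SUBSTITUTION, base=w
            )
    raise RejectionError(f"{w}: no legal substitution nonword in {max_draws} draws")


# --------------------------------------------------------------------------
# rendering and cue extraction


@dataclass(frozen=True)
class CueId:
    """Identifier of one discrete visual cue.

    A cue is the conjunction of a letter slot, a grid cell within the slot,
    an orientation bin and a contrast level. The string form
    ``s{slot}r{row}c{col}o{bin}l{level}`` is bijective with the tuple.
    """

    slot: int
    cell_row: int
    cell_col: int
    orientation_bin: int
    contrast_level: int

    def __str__(self) -> str:
        return (
            f"s{self.slot}r{self.cell_row}c{self.cell_col}"
            f"o{self.orientation_bin}l{self.contrast_level}"
        )

    _RE = re.compile(r"^s(\d+)r(\d+)c(\d+)o(\d+)l(\d+)$")

    @classmethod
    def parse(cls, s: str) -> "CueId":
        m = cls._RE.match(s)
        if not m:
            raise ValidationError(f"not a cue id: {s!r}")
        return cls(*(int(g) for g in m.groups()))


@dataclass(frozen=True)
class FeatureConfig:
    """Geometry and quantization of the visual cue inventory.

    Defaults give a 1,920-cue inventory (4 slots x 5x6 cells x 8
    orientation bins x 2 contrast levels); :meth:`large_scale` raises the
    grid and quantization so the inventory lands in the low tens of
    thousands. The analyses only require cues to be discrete and
    slot-tagged, not any particular count.
    """

    glyph_height_px: int = 40
    slot_width_px: int = 30
    cells_per_slot: tuple[int, int] = (5, 6)
    n_orientation_bins: int = 8
    n_contrast_levels: int = 2
    magnitude_thresholds: tuple[float, ...] = (0.5, 2.5)
    font_fixture_id: str = FONT_ID

    def __post_init__(self) -> None:
        rows, cols = self.cells_per_slot
        if min(self.glyph_height_px, self.slot_width_px, rows, cols) < 1:
            raise ValidationError("geometry fields must be positive")
        if self.n_orientation_bins < 1 or self.n_contrast_levels < 1:
            raise ValidationError("quantization fields must be positive")
        th = self.magnitude_thresholds
        if len(th) != self.n_contrast_levels:
            raise ValidationError(
                "need one magnitude threshold per contrast level"
            )
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValidationError("magnitude thresholds must be strictly ascending")
        if self.font_fixture_id != FONT_ID:
            raise ValidationError(f"unknown font fixture {self.font_fixture_id!r}")
        scale = min(
            (self.glyph_height_px - 2) // GLYPH_ROWS,
            (self.slot_width_px - 2) // GLYPH_COLS,
        )
        if scale < 1:
            raise ValidationError("slot too small for the packaged 5x7 font")

    @classmethod
    def large_scale(cls) -> "FeatureConfig":
        """A preset whose inventory size (14,336) is in the low tens of
        thousands, the scale at which such feature sets are typically run."""
        return cls(
            glyph_height_px=40,
            slot_width_px=30,
            cells_per_slot=(7, 8),
            n_orientation_bins=16,
            n_contrast_levels=4,
            magnitude_thresholds=(0.25, 0.75, 1.5, 3.0),
        )

    @property
    def inventory_size(self) -> int:
        rows, cols = self.cells_per_slot
        return (
            WORD_LENGTH
            * rows
            * cols
            * self.n_orientation_bins
            * self.n_contrast_levels
        )

    def inventory(self) -> Iterator[CueId]:
        rows, cols = self.cells_per_slot
        for slot, r, c, o, l in itertools.product(
            range(WORD_LENGTH),
            range(rows),
            range(cols),
            range(self.n_orientation_bins),
            range(self.n_contrast_levels),
        ):
            yield CueId(slot, r, c, o, l)


@dataclass(frozen=True)
class GlyphImage:
    """A rendered letter string: grayscale raster plus slot intervals."""

    pixels: np.ndarray  # (height, width), float in [0, 1], origin top-left
    slot_bounds: tuple[tuple[int, int], ...]  # half-open column intervals

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def render(s: str, cfg: FeatureConfig = FeatureConfig()) -> GlyphImage:
    """Rasterize a four-letter string with the packaged bitmap font.

    Each glyph is nearest-neighbour upscaled by an integer factor and
    centred inside its slot with at least one blank pixel of margin, so
    rendering is deterministic and strictly slot-confined.
    """
    validate_letter_string(s, where="render")
    h, sw = cfg.glyph_height_px, cfg.slot_width_px
    scale = min((h - 2) // GLYPH_ROWS, (sw - 2) // GLYPH_COLS)
    gh, gw = GLYPH_ROWS * scale, GLYPH_COLS * scale
    y0 = (h - gh) // 2
    img = np.zeros((h, sw * WORD_LENGTH), dtype=np.float64)
    bounds = []
    for slot, ch in enumerate(s):
        if ch not in FONT_5X7:
            raise ValidationError(f"glyph {ch!r} missing from font fixture")
        bitmap = np.array(
            [[1.0 if px == "#" else 0.0 for px in row] for row in FONT_5X7[ch]]
        )
        big = np.kron(bitmap, np.ones((scale, scale)))
        x0 = slot * sw + (sw - gw) // 2
        img[y0 : y0 + gh, x0 : x0 + gw] = big
        bounds.append((slot * sw, (slot + 1) * sw))
    return GlyphImage(pixels=img, slot_bounds=tuple(bounds))


def _cell_edges(n_px: int, n_cells: int) -> np.ndarray:
    """Deterministic near-equal partition of ``n_px`` pixels into cells."""
    return np.round(np.linspace(0, n_px, n_cells + 1)).astype(int)


def extract_cues(img: GlyphImage, cfg: FeatureConfig = FeatureConfig()) -> frozenset[CueId]:
    """Extract the set of active discrete orientation/contrast cues.

    Per slot and grid cell: central-difference gradients (zero padding),
    unsigned orientation (theta and theta+180 deg identified) quantized
    into ``n_orientation_bins``, gradient magnitudes summed per bin, and
    one cue emitted per (cell, bin, level) whose summed magnitude exceeds
    that level's threshold. Purely deterministic.
    """
    h, sw = cfg.glyph_height_px, cfg.slot_width_px
    px = img.pixels
    if px.shape != (h, sw * WORD_LENGTH):
        raise ValidationError(
            f"raster shape {px.shape} does not match config geometry "
            f"({h}, {sw * WORD_LENGTH})"
        )
    expected_bounds = tuple((i * sw, (i + 1) * sw) for i in range(WORD_LENGTH))
    if img.slot_bounds != expected_bounds:
        raise ValidationError("slot bounds do not match config geometry")

    padded = np.pad(px, 1)
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)  # unsigned orientation
    bins = np.minimum(
        (theta / (np.pi / cfg.n_orientation_bins)).astype(int),
        cfg.n_orientation_bins - 1,
    )

    rows, cols = cfg.cells_per_slot
    row_edges = _cell_edges(h, rows)
    col_edges = _cell_edges(sw, cols)
    row_idx = np.searchsorted(row_edges, np.arange(h), side="right") - 1
    active: set[CueId] = set()
    n_bins = cfg.n_orientation_bins
    for slot in range(WORD_LENGTH):
        sl = slice(slot * sw, (slot + 1) * sw)
        col_idx = np.searchsorted(col_edges, np.arange(sw), side="right") - 1
        cell_of = row_idx[:, None] * cols + col_idx[None, :]
        lin = cell_of * n_bins + bins[:, sl]
        sums = np.bincount(
            lin.ravel(), weights=mag[:, sl].ravel(), minlength=rows * cols * n_bins
        )
        hot = np.nonzero(sums > cfg.magnitude_thresholds[0])[0]
        for idx in hot:
            cell, obin = divmod(int(idx), n_bins)
            r, c = divmod(cell, cols)
            s_val = sums[idx]
            for level, thr in enumerate(cfg.magnitude_thresholds):
                if s_val > thr:
                    active.add(CueId(slot, r, c, obin, level))
    return frozenset(active)


def cue_cache(cfg: FeatureConfig = FeatureConfig()):
    """Return a memoized ``string -> frozenset[str]`` cue mapper.

    Because rendering confines every glyph to its slot (with blank margin)
    and gradients are local, a string's cue set decomposes exactly into
    the union of per-(slot, letter) patterns; the mapper therefore caches
    26 x 4 letter patterns and composes them, which makes large stimulus
    pools cheap. Cue ids are returned in their string form, which is what
    the learner and all serialization use.
    """
    letter_memo: dict[tuple[int, str], frozenset[str]] = {}

    def _letter_pattern(slot: int, ch: str) -> frozenset[str]:
        got = letter_memo.get((slot, ch))
        if got is None:
            all_cues = extract_cues(render(ch * WORD_LENGTH, cfg), cfg)
            by_slot: dict[int, set[str]] = {s: set() for s in range(WORD_LENGTH)}
            for c in all_cues:
                by_slot[c.slot].add(str(c))
            for s in range(WORD_LENGTH):
                letter_memo[(s, ch)] = frozenset(by_slot[s])
            got = letter_memo[(slot, ch)]
        return got

    memo: dict[str, frozenset[str]] = {}

    def cues_of(s: str) -> frozenset[str]:
        got = memo.get(s)
        if got is None:
            validate_letter_string(s, where="cue_cache")
            got = frozenset().union(
                *(_letter_pattern(i, ch) for i, ch in enumerate(s))
            )
            memo[s] = got
        return got

    return cues_of


def write_cue_inventory(cfg: FeatureConfig, path: str | Path) -> None:
    """Write the cue-inventory manifest CSV (cue_id, slot, row, col, bin, level)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["cue_id", "slot", "row", "col", "bin", "level"])
        for cue in cfg.inventory():
            wr.writerow(
                [str(cue), cue.slot, cue.cell_row, cue.cell_col,
                 cue.orientation_bin, cue.contrast_level]
            )


def write_cue_activations(
    strings: Sequence[str], cfg: FeatureConfig, path: str | Path
) -> None:
    """Write active cues as CSV triplets (stimulus, cue_id, 1)."""
    cues_of = cue_cache(cfg)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["stimulus", "cue_id", "value"])
        for s in strings:
            for cue in sorted(cues_of(s)):
                wr.writerow([s, cue, 1])
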