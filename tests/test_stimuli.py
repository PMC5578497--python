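"""Lexicon handling, nonword derivation, rendering and cue extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from widelex.stimuli import (
    CueId,
    Derivation,
    FeatureConfig,
    GlyphImage,
    Lexicon,
    Outcome,
    RejectionError,
    StimulusItem,
    ValidationError,
    cue_cache,
    extract_cues,
    load_lexicon,
    make_substitution_nonword,
    make_transposition_nonword,
    ngrams,
    render,
)

ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# -- lexicon ---------------------------------------------------------------


def test_load_lexicon_preserves_order_and_dedupes(tmp_path):
    p = tmp_path / "lex.txt"
    p.write_text("TORE\nWEND\nBOOR\n")
    assert load_lexicon(p).entries == ("TORE", "WEND", "BOOR")
    p.write_text("tore\nTORE\n")
    assert load_lexicon(p).entries == ("TORE",)


def test_load_lexicon_rejects_bad_token_with_line_number(tmp_path):
    p = tmp_path / "lex.txt"
    p.write_text("TORE\nTOR\n")
    with pytest.raises(ValidationError, match=":2"):
        load_lexicon(p)


def test_bundled_lexicon_contains_flagship_words(lex):
    for w in ("TORE", "WEND", "BOOR", "TARE", "KRIS"):
        assert w in lex


# -- n-grams ---------------------------------------------------------------


@pytest.mark.parametrize(
    "s,n,expected",
    [
        ("TORE", 3, ["TOR", "ORE"]),
        ("TORE", 2, ["TO", "OR", "RE"]),
        ("TORE", 4, ["TORE"]),
        ("AAAA", 2, ["AA", "AA", "AA"]),
    ],
)
def test_ngrams(s, n, expected):
    assert ngrams(s, n) == expected


def test_ngrams_rejects_bad_n():
    with pytest.raises(ValidationError):
        ngrams("TORE", 5)


# -- nonword derivation ----------------------------------------------------


def test_transposition_swaps_middle_letters(small_lex):
    item = make_transposition_nonword("TORE", small_lex)
    assert item.string == "TROE"
    assert item.derivation is Derivation.TRANSPOSITION
    assert item.base == "TORE"
    assert item.lexicality is Outcome.NONWORD
    assert make_transposition_nonword("WEND", small_lex).string == "WNED"


def test_transposition_rejects_identical_middles(small_lex):
    with pytest.raises(RejectionError):
        make_transposition_nonword("BOOR", small_lex)


def test_transposition_rejects_when_swap_is_a_word():
    lex = Lexicon(["ABCD", "ACBD"])
    with pytest.raises(RejectionError):
        make_transposition_nonword("ABCD", lex)


def test_substitution_candidate_set_membership(small_lex, rng):
    """Brute-force enumeration of the legal candidate set."""
    vowels, consonants = set("AEIOU"), set(ALPHABET) - set("AEIOU")
    legal = {
        "T" + v + c + "E"
        for v in vowels - {"O"}
        for c in consonants - {"R"}
        if ("T" + v + c + "E") not in small_lex
    }
    for _ in range(25):
        item = make_substitution_nonword("TORE", small_lex, rng)
        assert item.string in legal
        assert item.derivation is Derivation.SUBSTITUTION
        assert item.base == "TORE"


def test_substitution_is_reproducible(small_lex):
    a = make_substitution_nonword("TORE", small_lex, np.random.default_rng(7))
    b = make_substitution_nonword("TORE", small_lex, np.random.default_rng(7))
    assert a == b


def test_derived_item_invariants():
    with pytest.raises(ValidationError):
        StimulusItem("TROE", Outcome.WORD, Derivation.TRANSPOSITION, base="TORE")
    with pytest.raises(ValidationError):
        StimulusItem("TORE", Outcome.NONWORD, Derivation.BASE)


# -- rendering -------------------------------------------------------------


def test_render_is_deterministic_and_slot_confined():
    cfg = FeatureConfig()
    a = render("TORE", cfg)
    b = render("TORE", cfg)
    assert np.array_equal(a.pixels, b.pixels)
    c = render("TARE", cfg)
    # differ only within slot 1's columns
    lo, hi = a.slot_bounds[1]
    diff_cols = np.nonzero((a.pixels != c.pixels).any(axis=0))[0]
    assert diff_cols.size > 0
    assert diff_cols.min() >= lo and diff_cols.max() < hi


def test_render_rejects_invalid_strings():
    with pytest.raises(ValidationError):
        render("")
    with pytest.raises(ValidationError):
        render("tore")


# -- cue extraction --------------------------------------------------------


def _brute_force_cues(img, cfg):
    """Independent naive reimplementation of the extraction contract."""
    h, sw = cfg.glyph_height_px, cfg.slot_width_px
    px = np.pad(img.pixels, 1)
    rows, cols = cfg.cells_per_slot
    re_ = np.round(np.linspace(0, h, rows + 1)).astype(int)
    ce = np.round(np.linspace(0, sw, cols + 1)).astype(int)
    sums = {}
    for y in range(h):
        for x in range(img.width):
            gx = (px[y + 1, x + 2] - px[y + 1, x]) / 2
            gy = (px[y + 2, x + 1] - px[y, x + 1]) / 2
            mag = np.hypot(gx, gy)
            if mag == 0:
                continue
            theta = np.arctan2(gy, gx) % np.pi
            b = min(int(theta / (np.pi / cfg.n_orientation_bins)),
                    cfg.n_orientation_bins - 1)
            slot, xs = divmod(x, sw)
            r = int(np.searchsorted(re_, y, side="right")) - 1
            c = int(np.searchsorted(ce, xs, side="right")) - 1
            sums[(slot, r, c, b)] = sums.get((slot, r, c, b), 0.0) + mag
    out = set()
    for (slot, r, c, b), s in sums.items():
        for lvl, thr in enumerate(cfg.magnitude_thresholds):
            if s > thr:
                out.add(CueId(slot, r, c, b, lvl))
    return frozenset(out)


@pytest.mark.parametrize("s", ["TORE", "KRIS", "EFTD", "ULNX"])
def test_extract_cues_matches_brute_force(s):
    cfg = FeatureConfig()
    img = render(s, cfg)
    assert extract_cues(img, cfg) == _brute_force_cues(img, cfg)


def test_extract_cues_empty_on_blank_raster():
    cfg = FeatureConfig()
    img = GlyphImage(
        pixels=np.zeros((cfg.glyph_height_px, cfg.slot_width_px * 4)),
        slot_bounds=tuple((i * cfg.slot_width_px, (i + 1) * cfg.slot_width_px)
                          for i in range(4)),
    )
    assert extract_cues(img, cfg) == frozenset()


def test_vertical_bar_activates_only_horizontal_gradient_bins():
    """A vertical bar's gradients are 0-degree-normal except at its ends."""
    cfg = FeatureConfig()
    px = np.zeros((cfg.glyph_height_px, cfg.slot_width_px * 4))
    px[8:32, 5] = 1.0  # bar inside slot 0
    img = GlyphImage(
        pixels=px,
        slot_bounds=tuple((i * cfg.slot_width_px, (i + 1) * cfg.slot_width_px)
                          for i in range(4)),
    )
    active = extract_cues(img, cfg)
    assert active == _brute_force_cues(img, cfg)
    assert active and all(c.slot == 0 for c in active)
    mid_bin = cfg.n_orientation_bins // 2  # 90-degree bin from the bar ends
    assert {c.orientation_bin for c in active} <= {0, mid_bin}
    bin0_cells = sum(c.orientation_bin == 0 for c in active)
    assert bin0_cells > sum(c.orientation_bin == mid_bin for c in active)


def test_extraction_geometry_mismatch_is_an_error():
    cfg = FeatureConfig()
    img = GlyphImage(pixels=np.zeros((10, 10)), slot_bounds=((0, 10),))
    with pytest.raises(ValidationError):
        extract_cues(img, cfg)


def test_cue_inventory_size_and_membership(cues):
    cfg = FeatureConfig()
    inventory = set(str(c) for c in cfg.inventory())
    assert len(inventory) == cfg.inventory_size == 1920
    for s in ("TORE", "IMMF"):
        assert cues(s) <= inventory
    big = FeatureConfig.large_scale()
    assert 10_000 <= big.inventory_size < 100_000


def test_slot_locality_of_cues(cues):
    """Strings differing in one letter differ only in that slot's cues."""
    for a, b, slot in [("TORE", "TARE", 1), ("TORE", "BORE", 0), ("WEND", "WENT", 3)]:
        diff = cues(a) ^ cues(b)
        assert diff
        assert {CueId.parse(c).slot for c in diff} == {slot}


def test_all_letters_have_distinct_cue_patterns(cues):
    pats = {ch: frozenset(c for c in cues(ch * 4) if c.startswith("s0"))
            for ch in ALPHABET}
    assert len(set(pats.values())) == 26


def test_cue_cache_matches_direct_extraction(rng):
    cfg = FeatureConfig()
    mapper = cue_cache(cfg)
    for _ in range(20):
        s = "".join(ALPHABET[i] for i in rng.integers(0, 26, 4))
        direct = frozenset(str(c) for c in extract_cues(render(s, cfg), cfg))
        assert mapper(s) == direct


def test_transposition_more_cue_similar_than_substitution(lex, cues, rng):
    """Sample-mean symmetric-difference inequality over >= 100 words."""
    dt, ds, n = [], [], 0
    for w in lex:
        try:
            t = make_transposition_nonword(w, lex)
            s = make_substitution_nonword(w, lex, rng)
        except RejectionError:
            continue
        cw = cues(w)
        dt.append(len(cw ^ cues(t.string)))
        ds.append(len(cw ^ cues(s.string)))
        n += 1
        if n >= 150:
            break
    assert n >= 100
    assert np.mean(dt) <= np.mean(ds)


# -- cue id round trip -----------------------------------------------------


@settings(max_examples=50, derandomize=True)
@given(
    st_hyp.integers(0, 3),
    st_hyp.integers(0, 9),
    st_hyp.integers(0, 9),
    st_hyp.integers(0, 15),
    st_hyp.integers(0, 3),
)
def test_cue_id_string_form_is_bijective(slot, r, c, o, l):
    cue = CueId(slot, r, c, o, l)
    assert CueId.parse(str(cue)) == cue
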