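"""Deterministic synthetic vocabularies for the record simulator.

The pools play the role a name-generation library would play in a real
administrative-data emulator: fixed, finite vocabularies of person names,
street names, and cities that records are sampled from.  They are built
once from a constant internal seed so the vocabulary itself is stable
across runs and platforms; only the *sampling* of records from the pools
uses the caller's seed.

All strings are uppercase A–Z (plus spaces in street/city names), so
freshly generated records are already in cleaned form.
"""

from __future__ import annotations

import functools

import numpy as np

# Constant pool seed: the vocabulary is part of the package definition,
# not of any particular simulation run.
_POOL_SEED = 160229

_ONSETS = [
    "B", "BR", "C", "CH", "CL", "D", "DR", "F", "FR", "G", "GR", "H",
    "J", "K", "KR", "L", "M", "N", "P", "PR", "QU", "R", "S", "SH",
    "SL", "ST", "T", "TH", "TR", "V", "W", "Y", "Z",
]
_VOWELS = ["A", "E", "I", "O", "U", "AI", "EE", "IA", "IO", "OO", "OU", "EA"]
_CODAS = ["", "", "N", "R", "S", "L", "T", "M", "D", "NN", "TT", "NE", "TH", "CK"]

_SURNAME_SUFFIXES = [
    "SON", "S", "EZ", "MAN", "BERG", "TON", "FIELD", "WOOD", "STEIN",
    "LEY", "FORD", "WELL", "ER", "INS", "DALE",
]
_CITY_SUFFIXES = ["VILLE", "TON", "FIELD", "DALE", "WOOD", "BEACH", "SPRINGS", "CITY"]
_STREET_TYPES = ["ST", "AVE", "RD", "LN", "DR", "BLVD", "CT", "WAY"]

# California ZIP codes span 90001-96162.  This contiguous range is a
# synthetic stand-in for the official (discontiguous) list; the simulator
# only requires a fixed finite pool sampled with replacement.
CA_ZIP_CODES = tuple(str(z) for z in range(90001, 96163))


def _syllable_batch(rng: np.random.Generator, size: int) -> np.ndarray:
    on = rng.choice(_ONSETS, size=size)
    vo = rng.choice(_VOWELS, size=size)
    co = rng.choice(_CODAS, size=size)
    out = np.char.add(np.char.add(on.astype("U8"), vo), co)
    return out


def _build_pool(rng: np.random.Generator, size: int, maker) -> np.ndarray:
    """Draw candidate strings until `size` distinct ones exist; order is
    the (deterministic) order of first appearance."""
    seen: dict[str, None] = {}
    while len(seen) < size:
        for s in maker(rng, 4 * size):
            if s not in seen:
                seen[s] = None
                if len(seen) == size:
                    break
    return np.array(list(seen), dtype="U32")


def _first_name_maker(rng: np.random.Generator, size: int) -> np.ndarray:
    a = _syllable_batch(rng, size)
    b = _syllable_batch(rng, size)
    two = rng.random(size) < 0.85
    names = np.where(two, np.char.add(a, np.char.lower(b)), a)
    return np.char.upper(names)


def _surname_maker(rng: np.random.Generator, size: int) -> np.ndarray:
    base = _syllable_batch(rng, size)
    suf = rng.choice(_SURNAME_SUFFIXES, size=size)
    extra = _syllable_batch(rng, size)
    long = rng.random(size) < 0.35
    base = np.where(long, np.char.add(base, extra), base)
    return np.char.upper(np.char.add(base, suf))


def _city_maker(rng: np.random.Generator, size: int) -> np.ndarray:
    base = _syllable_batch(rng, size)
    suf = rng.choice(_CITY_SUFFIXES, size=size)
    return np.char.upper(np.char.add(base, suf))


def _street_name_maker(rng: np.random.Generator, size: int) -> np.ndarray:
    base = _syllable_batch(rng, size)
    extra = _syllable_batch(rng, size)
    long = rng.random(size) < 0.4
    name = np.where(long, np.char.add(base, extra), base)
    suf = rng.choice(_STREET_TYPES, size=size)
    return np.char.add(np.char.upper(name), np.char.add(" ", suf))


@functools.lru_cache(maxsize=None)
def name_pools(
    n_first: int = 6000,
    n_surname: int = 12000,
    n_city: int = 600,
    n_street: int = 4000,
) -> dict[str, np.ndarray]:
    """Return the fixed vocabulary pools, keyed by role.

    Pool sizes are configurable because real administrative data carries
    more name variety than any synthetic pool; the defaults satisfy the
    package's simulation design (>= 5,000 first names, >= 10,000 surnames).
    """
    rng = np.random.Generator(np.random.PCG64(_POOL_SEED))
    return {
        "first": _build_pool(rng, n_first, _first_name_maker),
        "surname": _build_pool(rng, n_surname, _surname_maker),
        "city": _build_pool(rng, n_city, _city_maker),
        "street": _build_pool(rng, n_street, _street_name_maker),
    }
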