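"""Shared fixtures: hand-built toy proteome and a random-proteome builder.

The random builder is intentionally independent of the synth module: it
exercises the data model and I/O layer with arbitrary (not biologically
structured) annotations, so the round-trip and oracle tests do not share
code with the generator they sometimes check.
"""

import string

import numpy as np
import pytest

from protannot import Proteome
from protannot.core import CANONICAL_ALPHABET

ALPHABET = sorted(CANONICAL_ALPHABET)
DOMAIN_TYPES = ["IDR", "PF00001", "coil", "LCD"]
SITE_TYPES = ["phospho", "acetyl", "methyl"]
KEY_CHARS = string.ascii_lowercase + string.digits + "_"


def random_attributes(rng, max_items=3):
    out = {}
    for _ in range(int(rng.integers(0, max_items + 1))):
        key = "".join(rng.choice(list(KEY_CHARS), size=int(rng.integers(1, 8))))
        # values may contain ':' — attribute tokens split on the first colon only
        value_chars = list(KEY_CHARS + ":.-")
        value = "".join(rng.choice(value_chars, size=int(rng.integers(0, 10))))
        out[key] = value
    return out


def random_proteome(
    rng,
    n_proteins=5,
    min_len=5,
    max_len=50,
    max_domains=6,
    max_sites=8,
    with_tracks=True,
    with_attributes=True,
):
    """A proteome with arbitrary random annotations for round-trip and
    oracle tests."""
    proteome = Proteome()
    for i in range(n_proteins):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(ALPHABET, size=length))
        protein = proteome.add_protein(f"P{i + 1:03d}", seq)
        for _ in range(int(rng.integers(0, max_domains + 1))):
            start = int(rng.integers(1, length + 1))
            stop = int(rng.integers(start, length + 1))
            dtype = str(rng.choice(DOMAIN_TYPES))
            protein.add_domain(start, stop, dtype, random_attributes(rng))
        for _ in range(int(rng.integers(0, max_sites + 1))):
            pos = int(rng.integers(1, length + 1))
            stype = str(rng.choice(SITE_TYPES))
            protein.add_site(pos, stype, protein.residue(pos),
                             float(np.round(rng.normal(), 6)),
                             random_attributes(rng))
        if with_tracks:
            if rng.random() < 0.8:
                protein.add_track("rsa", values=np.round(rng.random(length), 4))
            if rng.random() < 0.5:
                protein.add_track("ss", symbols=rng.choice(["H", "E", "C"], size=length))
        if with_attributes and rng.random() < 0.7:
            protein.attributes.update(random_attributes(rng))
            protein.attributes.setdefault(
                "abundance", repr(float(np.round(10 ** rng.normal(2, 1), 4)))
            )
    return proteome


def assert_proteomes_equal(a: Proteome, b: Proteome, tracks=("rsa", "ss")):
    """Annotation-level equality: identities, sequences, domains, sites,
    tracks and attributes (protein display names excluded)."""
    assert a.unique_ids == b.unique_ids
    for pa_, pb in zip(a, b):
        assert pa_.sequence == pb.sequence
        assert pa_.domains == pb.domains
        assert pa_.sites == pb.sites
        assert pa_.attributes == pb.attributes
        assert sorted(pa_.tracks) == sorted(pb.tracks)
        for name in pa_.tracks:
            assert pa_.track(name) == pb.track(name)


@pytest.fixture
def toy():
    from protannot import worked_toy_proteome

    return worked_toy_proteome()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
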