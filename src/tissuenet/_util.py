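"""Small shared helpers: canonical gene-pair keys and logging setup."""

from __future__ import annotations

import logging
from typing import Hashable, Iterable, Tuple

Pair = Tuple[str, str]

log = logging.getLogger("tissuenet")


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered pair: lexicographically sorted, distinct genes.

    All gene pairs in the package are undirected; every map keyed by pairs
    uses this canonical form so that (i, j) and (j, i) hit the same entry.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(genes: Iterable[str]) -> Iterable[Pair]:
    """Yield every canonical unordered pair over a gene collection."""
    ordered = sorted(set(genes))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            yield (a, b)


def check_unique(items: Iterable[Hashable], what: str) -> None:
    seen = set()
    for x in items:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)
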