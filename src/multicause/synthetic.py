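"""Synthetic death-certificate populations with known generating parameters.

Real multiple-cause mortality files are rarely shareable, so every pipeline
stage here is exercised on simulated certificates whose truth is known.
The generator draws, per death, one underlying-cause category from a
categorical distribution and then mentions each other category as a
contributing cause independently with a UCoD-conditional probability
m[u][c].  That pairwise structure is exactly what the data-driven x-matrix
estimates, so parameter recovery (x̂_uc → m[u][c]) is directly checkable
against binomial sampling error.

Also provided is the canonical ten-record worked example with four causes
A–D used throughout the documentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .certificates import Certificate
from .mapping import CategoryMapping

__all__ = [
    "GeneratorConfig",
    "generate",
    "table1_fixture",
    "fixture_mapping",
    "FIXTURE_CATEGORIES",
]

_PROB_TOL = 1e-12


@dataclass
class GeneratorConfig:
    """Parameters of the certificate generator.

    ``categories`` are analysis-category labels with one representative
    ICD-10 code each (``codes``); generated certificates carry the
    representative code of each drawn category.  ``ucod_probs`` is the
    categorical UCoD distribution; ``mention_probs[u][c]`` the probability
    that a death with UCoD category u mentions c as a contributing cause
    (zero diagonal).  At most ``max_ccods`` contributing causes survive per
    certificate (a uniform random subset when exceeded); keep it at or
    above the number of categories when parameter recovery matters, so
    truncation never binds.  Optional ``sex_probs`` and ``age_range``
    (inclusive integer bounds, uniform) add demographic strata.
    """

    categories: list[str]
    codes: list[str]
    ucod_probs: Sequence[float]
    mention_probs: Sequence[Sequence[float]]
    max_ccods: int = 1_000_000
    sex_probs: dict[str, float] | None = None
    age_range: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.categories)
        if len(self.codes) != k:
            raise ValueError("codes must parallel categories")
        self.ucod_probs = np.asarray(self.ucod_probs, dtype=float)
        self.mention_probs = np.asarray(self.mention_probs, dtype=float)
        if self.ucod_probs.shape != (k,):
            raise ValueError("ucod_probs must have one entry per category")
        if abs(self.ucod_probs.sum() - 1.0) > _PROB_TOL or (self.ucod_probs < 0).any():
            raise ValueError("ucod_probs must be a probability vector summing to 1")
        if self.mention_probs.shape != (k, k):
            raise ValueError("mention_probs must be a square matrix over categories")
        if ((self.mention_probs < 0) | (self.mention_probs > 1)).any():
            raise ValueError("mention_probs entries must lie in [0, 1]")
        if np.diagonal(self.mention_probs).any():
            raise ValueError("mention_probs must have a zero diagonal")
        if self.max_ccods < 0:
            raise ValueError("max_ccods must be non-negative")
        if self.sex_probs is not None:
            total = sum(self.sex_probs.values())
            if abs(total - 1.0) > _PROB_TOL or any(v < 0 for v in self.sex_probs.values()):
                raise ValueError("sex_probs must be a probability vector summing to 1")
        if self.age_range is not None and self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")

    # -- config file I/O ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if raw.get("age_range") is not None:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "categories": list(self.categories),
            "codes": list(self.codes),
            "ucod_probs": [float(v) for v in self.ucod_probs],
            "mention_probs": [[float(v) for v in row] for row in self.mention_probs],
            "max_ccods": int(self.max_ccods),
            "sex_probs": self.sex_probs,
            "age_range": list(self.age_range) if self.age_range else None,
            "seed": int(self.seed),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def generate(config: GeneratorConfig, n: int) -> list[Certificate]:
    """Draw ``n`` certificates from the generator, reproducibly from its seed.

    The UCoD is emitted as a single Part I line; contributing causes go to
    Part II (position within the certificate does not matter to the method
    once the extraction rule is fixed).  The same config always produces
    the same population.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(config.seed)
    k = len(config.categories)
    codes = config.codes
    ucods = rng.choice(k, size=n, p=config.ucod_probs)
    mention_p = np.asarray(config.mention_probs)
    mentions = rng.random((n, k)) < mention_p[ucods]
    mentions[np.arange(n), ucods] = False

    sexes: list[str | None]
    if config.sex_probs is not None:
        labels = list(config.sex_probs)
        draws = rng.choice(len(labels), size=n, p=list(config.sex_probs.values()))
        sexes = [labels[d] for d in draws]
    else:
        sexes = [None] * n
    if config.age_range is not None:
        lo, hi = config.age_range
        ages = rng.integers(lo, hi + 1, size=n)
    else:
        ages = None

    width = len(str(n))
    certs: list[Certificate] = []
    for i in range(n):
        cc = np.flatnonzero(mentions[i])
        if cc.size > config.max_ccods:
            cc = rng.choice(cc, size=config.max_ccods, replace=False)
            cc.sort()
        u = int(ucods[i])
        certs.append(
            Certificate(
                id=f"S{i + 1:0{width}d}",
                ucod=codes[u],
                part1=[[codes[u]]],
                part2=[codes[int(c)] for c in cc],
                ucod_position=(0, 0),
                sex=sexes[i],
                age_years=None if ages is None else int(ages[i]),
            )
        )
    return certs


# ---------------------------------------------------------------------------
# The ten-record worked example
# ---------------------------------------------------------------------------

#: Category labels of the four-cause worked example.
FIXTURE_CATEGORIES: tuple[str, ...] = ("A", "B", "C", "D")

# Representative codes: chapter letter matches the category label.
_FIXTURE_CODES = {"A": "A00", "B": "B00", "C": "C00", "D": "D00"}

# (UCoD, [CCoDs as listed]) for the ten hypothetical deaths; duplicate
# mentions (record 8) are deliberate and must collapse during resolution.
_FIXTURE_ROWS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("A", ()),
    ("A", ("A",)),
    ("A", ("B",)),
    ("A", ("B", "C")),
    ("A", ("A", "C")),
    ("B", ("A", "D")),
    ("B", ("C", "D")),
    ("C", ("A", "C", "A")),
    ("D", ("B", "C")),
    ("D", ("A", "B", "C")),
)


def table1_fixture() -> list[Certificate]:
    """The ten hypothetical death records with four causes A, B, C and D.

    Returned as record-axis certificates (UCoD first, remaining causes as
    listed, duplicates preserved) using placeholder codes A00–D00 that
    :func:`fixture_mapping` maps onto categories A–D.
    """
    return [
        Certificate(
            id=str(i),
            ucod=_FIXTURE_CODES[ucod],
            part1=[],
            part2=[_FIXTURE_CODES[c] for c in ccods],
            ucod_position=None,
        )
        for i, (ucod, ccods) in enumerate(_FIXTURE_ROWS, start=1)
    ]


def fixture_mapping() -> CategoryMapping:
    """Four single-letter categories A-D for the worked example."""
    return CategoryMapping(
        entries=[(letter, letter) for letter in FIXTURE_CATEGORIES],
        categories=list(FIXTURE_CATEGORIES),
    )
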