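"""Nearest-neighbor energy model for hairpin folding and duplex hybridization.

A deliberately simplified Turner-style model: Watson-Crick stack free energies
(kcal/mol, 37 degC) are tabulated; stacks involving G:U wobbles use three
category constants; hairpin/bulge/internal loops carry positive size-dependent
penalties with logarithmic extrapolation beyond the tabulated sizes.  The
table ships as a versioned data file so results are reproducible across
releases.  Multibranch loops are outside the model — the pipeline only needs
single stem-loop geometry and a stability score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}
PAIRS = WC_PAIRS | GU_PAIRS


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in GU_PAIRS


def _load_table(name: str = "stack_energies_v1.tsv") -> dict:
    raw: dict[str, dict[str, float]] = {"stack": {}, "gu_stack": {},
                                        "hairpin": {}, "bulge": {},
                                        "internal": {}, "param": {}}
    text = resources.files("beanmir.data").joinpath(name).read_text()
    for line in text.splitlines()[1:]:
        kind, key, value = line.split("\t")
        raw[kind][key] = float(value)
    return raw


def _canonical(key: str) -> str:
    # "XY/ZW" == reading the opposite strand 5'->3': "WZ/YX"
    x, y, _, z, w = key
    rev = w + z + "/" + y + x
    return min(key, rev)


@dataclass
class FoldParams:
    """Energy parameters; defaults load the packaged versioned table."""

    table_version: str = "stack_energies_v1.tsv"
    min_loop: int = 3
    max_loop_side: int = 6      # largest bulge / internal-loop side considered
    _raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._raw:
            self._raw = _load_table(self.table_version)
        self.min_loop = int(self._raw["param"].get("min_loop", self.min_loop))
        self._ln = self._raw["param"]["ln_extrapolation"]
        self.duplex_mismatch = self._raw["param"]["duplex_mismatch"]
        self.duplex_bulge_nt = self._raw["param"]["duplex_bulge_nt"]
        self._stacks: dict[str, float] = {
            _canonical(k): v for k, v in self._raw["stack"].items()}

    def stack_energy(self, p1: tuple[str, str], p2: tuple[str, str]) -> float:
        """Free energy of stacking inner pair p2 on outer pair p1.

        p1=(x1,y1), p2=(x2,y2) with x on the 5' strand: 5'-x1 x2-3' paired
        3'-y1 y2-5'.  Symmetric under strand reversal.
        """
        if p1 not in PAIRS or p2 not in PAIRS:
            raise ValueError(f"not a legal pair stack: {p1}, {p2}")
        gu1, gu2 = p1 in GU_PAIRS, p2 in GU_PAIRS
        if gu1 or gu2:
            g = self._raw["gu_stack"]
            if gu1 and gu2:
                return g["GU_GU"]
            wc = p2 if gu1 else p1
            return g["GU_GC"] if wc in {("G", "C"), ("C", "G")} else g["GU_AU"]
        key = _canonical(p1[0] + p2[0] + "/" + p1[1] + p2[1])
        return self._stacks[key]

    def _looped(self, table: dict[str, float], n: int, nmax: int) -> float:
        if n <= nmax:
            return table[str(n)]
        return table[str(nmax)] + self._ln * math.log(n / nmax)

    def hairpin_penalty(self, n: int) -> float:
        if n < self.min_loop:
            raise ValueError(f"hairpin loop of {n} < min_loop {self.min_loop}")
        return self._looped(self._raw["hairpin"], n, 9)

    def bulge_penalty(self, n: int) -> float:
        if n < 1:
            raise ValueError("bulge size must be >= 1")
        return self._looped(self._raw["bulge"], n, 6)

    def internal_penalty(self, n: int) -> float:
        if n < 2:
            raise ValueError("internal loop total size must be >= 2")
        return self._looped(self._raw["internal"], n, 6)

    def two_loop_energy(self, n5: int, n3: int) -> float:
        """Energy of the loop between two pairs with n5/n3 unpaired bases."""
        if n5 == 0 and n3 == 0:
            raise ValueError("adjacent pairs stack; use stack_energy")
        if n5 == 0 or n3 == 0:
            return self.bulge_penalty(n5 + n3)
        return self.internal_penalty(n5 + n3)
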