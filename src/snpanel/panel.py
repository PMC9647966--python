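"""Marker-panel discernibility and randomized panel selection.

Each sample's calls over a fixed ordered panel are joined into a
genotype string of allele-pair tokens ("AA", "AG", ..., "NN" for
missing); the discernibility of a panel is

    discernibility = (number of distinct genotype strings) / (number of samples)

Minimal panels are found the way the original workflow does it: draw
many random k-subsets per size, score each, and keep the best — plus an
exhaustive mode over all subsets for small marker counts, used as the
optimum oracle.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .model import Call, GenotypeMatrix

MISSING_TOKEN = "NN"
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class GenotypeString:
    sample_id: str
    tokens: tuple[str, ...]

    @property
    def joined(self) -> str:
        return "|".join(self.tokens)


@dataclass(frozen=True)
class PanelResult:
    marker_ids: tuple[str, ...]
    n_unique: int
    n_samples: int

    @property
    def discernibility(self) -> float:
        return self.n_unique / self.n_samples

    @property
    def discernibility_exact(self) -> Fraction:
        return Fraction(self.n_unique, self.n_samples)


@dataclass(frozen=True)
class SimulationConfig:
    """Randomized-search settings: which panel sizes to try, how many
    random subsets per size (the workflow's published run used 5000, and
    10000 for the cumulative efficiency curve), and the RNG seed."""

    panel_sizes: tuple[int, ...]
    reps_per_size: int = 5000
    seed: int = 0
    missing_mode: str = "distinct"

    def __post_init__(self):
        object.__setattr__(self, "panel_sizes", tuple(self.panel_sizes))
        if self.reps_per_size < 1:
            raise ValueError("reps_per_size must be >= 1")
        if any(k < 1 for k in self.panel_sizes):
            raise ValueError("panel sizes must be >= 1")
        if self.missing_mode not in ("distinct", "wildcard"):
            raise ValueError(f"unknown missing_mode: {self.missing_mode!r}")


def _token(call: int, ref: str, alt: str) -> str:
    if call == Call.HOM_REF:
        return ref + ref
    if call == Call.HET:
        a, b = sorted((ref, alt))
        return a + b
    if call == Call.HOM_ALT:
        return alt + alt
    return MISSING_TOKEN


def genotype_string(
    matrix: GenotypeMatrix, sample: str, panel: Sequence[str]
) -> GenotypeString:
    """One sample's allele-pair token string over an ordered panel.

    Heterozygous tokens are alphabetically sorted so "AG" == "GA".
    """
    row = matrix.row(sample)
    tokens = []
    for mid in panel:
        j = matrix.marker_column_index(mid)
        m = matrix.markers[j]
        tokens.append(_token(int(row[j]), m.ref, m.alt))
    return GenotypeString(sample, tuple(tokens))


def _call_columns(matrix: GenotypeMatrix, panel: Sequence[str]) -> np.ndarray:
    idx = [matrix.marker_column_index(m) for m in panel]
    return matrix.calls[:, idx]


def _group_samples(sub: np.ndarray, missing_mode: str) -> list[list[int]]:
    """Partition sample indices into identical-genotype groups.

    distinct: MISSING is its own symbol; exact row equality.
    wildcard: MISSING matches any call, which is not transitive, so
    groups are connected components of the pairwise-compatibility graph.
    """
    n = sub.shape[0]
    if missing_mode == "distinct":
        seen: dict[bytes, list[int]] = {}
        for i in range(n):
            seen.setdefault(sub[i].tobytes(), []).append(i)
        return list(seen.values())
    # wildcard
    miss = sub == Call.MISSING
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            compatible = bool(np.all((sub[i] == sub[j]) | miss[i] | miss[j]))
            if compatible:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def discernibility(
    matrix: GenotypeMatrix,
    panel: Sequence[str],
    missing_mode: str = "distinct",
) -> PanelResult:
    """Score one marker subset: distinct genotype strings / samples."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must contain at least one marker")
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    groups = _group_samples(_call_columns(matrix, panel), missing_mode)
    return PanelResult(
        marker_ids=tuple(panel),
        n_unique=len(groups),
        n_samples=matrix.n_samples,
    )


@dataclass
class SizeBest:
    """Best result among the subsets tried at one panel size."""

    size: int
    n_tried: int
    best_n_unique: int
    n_samples: int
    best_subsets: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def best_discernibility(self) -> float:
        return self.best_n_unique / self.n_samples


def simulate_combinations(
    matrix: GenotypeMatrix, config: SimulationConfig
) -> dict[int, SizeBest]:
    """Randomized panel search: for each size k draw `reps_per_size`
    uniform k-subsets (without replacement within a draw, repeats
    allowed across draws), score each, and retain every subset achieving
    the size's maximum discernibility.

    Reproducible given the seed; best subsets are reported sorted.
    """
    rng = np.random.default_rng(config.seed)
    ids = matrix.marker_ids
    m = len(ids)
    out: dict[int, SizeBest] = {}
    for k in config.panel_sizes:
        if k > m:
            raise ValueError(f"panel size {k} exceeds marker count {m}")
        best: SizeBest | None = None
        subsets_at_best: set[tuple[str, ...]] = set()
        for _ in range(config.reps_per_size):
            pick = rng.choice(m, size=k, replace=False)
            subset = tuple(sorted(ids[j] for j in pick))
            res = discernibility(matrix, subset, config.missing_mode)
            if best is None or res.n_unique > best.best_n_unique:
                best = SizeBest(
                    size=k,
                    n_tried=config.reps_per_size,
                    best_n_unique=res.n_unique,
                    n_samples=res.n_samples,
                )
                subsets_at_best = {subset}
            elif res.n_unique == best.best_n_unique:
                subsets_at_best.add(subset)
        assert best is not None
        best.best_subsets = sorted(subsets_at_best)
        out[k] = best
    return out


def exhaustive_best(
    matrix: GenotypeMatrix,
    k: int,
    missing_mode: str = "distinct",
    max_markers: int = 20,
) -> SizeBest:
    """True optimum over all C(m, k) subsets; intended for small marker
    counts (refuses beyond `max_markers`)."""
    ids = matrix.marker_ids
    if len(ids) > max_markers:
        raise ValueError(
            f"exhaustive search limited to {max_markers} markers "
            f"(matrix has {len(ids)})"
        )
    best: SizeBest | None = None
    subsets_at_best: list[tuple[str, ...]] = []
    n_tried = 0
    for combo in itertools.combinations(ids, k):
        n_tried += 1
        res = discernibility(matrix, combo, missing_mode)
        if best is None or res.n_unique > best.best_n_unique:
            best = SizeBest(
                size=k,
                n_tried=0,
                best_n_unique=res.n_unique,
                n_samples=res.n_samples,
            )
            subsets_at_best = [combo]
        elif res.n_unique == best.best_n_unique:
            subsets_at_best.append(combo)
    if best is None:
        raise ValueError("no subsets of that size")
    best.n_tried = n_tried
    best.best_subsets = sorted(tuple(sorted(s)) for s in subsets_at_best)
    return best


def minimal_panel_size(
    matrix: GenotypeMatrix,
    config: SimulationConfig | None = None,
    exhaustive: bool = False,
) -> tuple[int, SizeBest]:
    """Smallest panel size whose best discernibility equals the
    full-panel discernibility; scans sizes ascending."""
    full = discernibility(
        matrix,
        matrix.marker_ids,
        (config.missing_mode if config else "distinct"),
    )
    sizes = range(1, matrix.n_markers + 1)
    for k in sizes:
        if exhaustive:
            best = exhaustive_best(
                matrix, k, config.missing_mode if config else "distinct"
            )
        else:
            cfg = SimulationConfig(
                panel_sizes=(k,),
                reps_per_size=config.reps_per_size if config else 5000,
                seed=(config.seed if config else 0) + k,
                missing_mode=config.missing_mode if config else "distinct",
            )
            best = simulate_combinations(matrix, cfg)[k]
        if best.best_n_unique == full.n_unique:
            return k, best
    raise AssertionError("full panel always achieves its own score")


def efficiency_curve(
    matrix: GenotypeMatrix, config: SimulationConfig
) -> list[dict]:
    """Per-size best discernibility (with the running maximum, which is
    non-decreasing by construction) for cumulative-efficiency plots."""
    results = simulate_combinations(matrix, config)
    rows = []
    running = 0.0
    for k in sorted(results):
        d = results[k].best_discernibility
        running = max(running, d)
        rows.append(
            {
                "size": k,
                "best_discernibility": d,
                "running_max": running,
                "n_tried": results[k].n_tried,
            }
        )
    return rows


def panel_hash(matrix: GenotypeMatrix, panel: Sequence[str]) -> str:
    """Stable identity of a panel: marker ids, positions, alleles and
    order. Fingerprints from different panels never compare silently."""
    h = hashlib.sha256()
    for mid in panel:
        m = matrix.marker(mid)
        h.update(f"{m.id}\t{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\n".encode())
    return h.hexdigest()[:12]
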