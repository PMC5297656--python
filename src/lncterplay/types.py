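"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates inside the package are 0-based, half-open
``[start, end)``.  Format-specific conventions (GTF 1-based closed, BED
0-based half-open) are converted at the I/O boundary and never leak in.
Sequences are stored as uppercase RNA (``T`` mapped to ``U``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GROUP_CASE = "case"
GROUP_CONTROL = "control"
VALID_GROUPS = frozenset({GROUP_CASE, GROUP_CONTROL})

BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_MRNA = "mRNA"
VALID_BIOTYPES = frozenset({BIOTYPE_LNCRNA, BIOTYPE_MRNA})

VALID_STRANDS = frozenset({"+", "-", "."})

RNA_ALPHABET = frozenset("ACGUN")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity table with a two-group design.

    ``values`` is a dense float matrix (probes in rows, arbitrary linear
    intensity units); ``groups`` maps every sample id to ``case`` or
    ``control``.  Both groups must be non-empty, all values finite and
    non-negative, and ids unique.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    groups: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.probe_ids)
        if dup:
            raise ValidationError(f"duplicate probe id(s): {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample id(s): {sorted(dup)}")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValidationError(f"sample(s) missing a group label: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in VALID_GROUPS}
        if bad:
            raise ValidationError(f"invalid group label(s): {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        for grp in (GROUP_CASE, GROUP_CONTROL):
            if not self.samples_in_group(grp):
                raise ValidationError(f"group '{grp}' has no samples")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in self.samples_in_group(group)]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, p in enumerate(self.probe_ids) if p in keep_set]
        return ExpressionMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            groups=dict(self.groups),
            values=self.values[idx, :].copy(),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Feature:
    """One annotated locus: a gene (mRNA) or a lncRNA."""

    feature_id: str
    biotype: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "."
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise ValidationError(
                f"{self.feature_id}: unknown biotype {self.biotype!r}"
            )
        if not self.chrom:
            raise ValidationError(f"{self.feature_id}: empty chromosome name")
        if not (0 <= self.start <= self.end):
            raise ValidationError(
                f"{self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"{self.feature_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class FeatureAnnotation:
    """Ordered collection of features with id-based lookup."""

    def __init__(self, features: Iterable[Feature]):
        self._features: dict[str, Feature] = {}
        for f in features:
            if f.feature_id in self._features:
                raise ValidationError(f"duplicate feature id: {f.feature_id}")
            self._features[f.feature_id] = f

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __getitem__(self, feature_id: str) -> Feature:
        try:
            return self._features[feature_id]
        except KeyError:
            raise KeyError(f"feature id not in annotation: {feature_id}") from None

    def by_biotype(self, biotype: str) -> list[Feature]:
        return [f for f in self if f.biotype == biotype]

    @property
    def lncrnas(self) -> list[Feature]:
        return self.by_biotype(BIOTYPE_LNCRNA)

    @property
    def genes(self) -> list[Feature]:
        return self.by_biotype(BIOTYPE_MRNA)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": f.feature_id,
                    "biotype": f.biotype,
                    "chrom": f.chrom,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "gene_symbol": f.gene_symbol,
                }
                for f in self
            ]
        )


@dataclass
class GeneSetCollection:
    """GMT-style flat gene sets over a declared gene universe."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")
            if self.universe is not None:
                stray = members - self.universe
                if stray:
                    raise ValidationError(
                        f"gene set {sid!r} has members outside the declared "
                        f"universe: {sorted(stray)[:5]}"
                    )
        for sid in self.sets:
            self.names.setdefault(sid, sid)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> set[str]:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression call.

    ``fold_change`` is the linear-scale case/control ratio of group means;
    ``direction`` is ``up``/``down``/``unchanged`` under the joint fold-change
    and t-test rule.
    """

    feature_id: str
    mean_control: float
    mean_case: float
    fold_change: float
    log2_fc: float
    p_value: float
    q_value: float
    direction: str


@dataclass(frozen=True)
class TargetPair:
    """A predicted (lncRNA, gene) regulatory link.

    cis pairs carry a genomic ``distance`` (nt, 0 if overlapping); trans pairs
    carry a duplex ``energy`` (kcal/mol) and are always inter-chromosomal.
    """

    lnc_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    distance: int | None = None
    energy: float | None = None
    lnc_direction: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cis", "trans"):
            raise ValidationError(f"invalid target mode: {self.mode!r}")
        if self.mode == "cis" and self.distance is None:
            raise ValidationError("cis pair requires a distance")
        if self.mode == "trans" and self.energy is None:
            raise ValidationError("trans pair requires an energy")


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one gene set in a query gene list."""

    set_id: str
    overlap: int          # k
    set_size: int         # K
    query_size: int       # n
    universe_size: int    # N
    p_hypergeom: float
    p_permutation: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= min(self.set_size, self.query_size)):
            raise ValidationError(
                f"{self.set_id}: overlap {self.overlap} inconsistent with "
                f"K={self.set_size}, n={self.query_size}"
            )


@dataclass
class SimulationTruth:
    """Ground truth planted by the synthetic-data generators."""

    seed: int
    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    cis_pairs: set[tuple[str, str]] = field(default_factory=set)
    trans_pairs: set[tuple[str, str]] = field(default_factory=set)
    decoy_pairs: set[tuple[str, str]] = field(default_factory=set)
    enriched_set_ids: set[str] = field(default_factory=set)
    low_intensity: set[str] = field(default_factory=set)

    def validate(self, annotation: FeatureAnnotation | None = None) -> None:
        if self.de_up & self.de_down:
            raise ValidationError(
                f"features planted both up and down: {self.de_up & self.de_down}"
            )
        if annotation is not None:
            for pairs in (self.cis_pairs, self.trans_pairs, self.decoy_pairs):
                for lnc, gene in pairs:
                    if lnc not in annotation or gene not in annotation:
                        raise ValidationError(
                            f"planted pair ({lnc}, {gene}) references unknown features"
                        )

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "de_up": sorted(self.de_up),
            "de_down": sorted(self.de_down),
            "cis_pairs": sorted(map(list, self.cis_pairs)),
            "trans_pairs": sorted(map(list, self.trans_pairs)),
            "decoy_pairs": sorted(map(list, self.decoy_pairs)),
            "enriched_set_ids": sorted(self.enriched_set_ids),
            "low_intensity": sorted(self.low_intensity),
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "SimulationTruth":
        return cls(
            seed=int(d["seed"]),
            de_up=set(d.get("de_up", ())),
            de_down=set(d.get("de_down", ())),
            cis_pairs={tuple(p) for p in d.get("cis_pairs", ())},
            trans_pairs={tuple(p) for p in d.get("trans_pairs", ())},
            decoy_pairs={tuple(p) for p in d.get("decoy_pairs", ())},
            enriched_set_ids=set(d.get("enriched_set_ids", ())),
            low_intensity=set(d.get("low_intensity", ())),
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups
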