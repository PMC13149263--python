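"""Declarative variable manifests for survey harmonization.

A manifest describes every raw cohort column that enters the risk pipeline:
its semantic kind (continuous / ordinal / binary / nominal), the direction in
which it loads on the risk index (+1 risk-increasing, -1 risk-decreasing,
0 excluded from the index), the plausible value range or allowed survey
codes, the harmonized name it maps to, and any refusal/sentinel codes that
must be treated as missing.  Manifests are the single source of truth for
semantic harmonization across survey sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

KINDS = ("continuous", "ordinal", "binary", "nominal")

#: Values always treated as missing, regardless of the per-variable sentinels.
DEFAULT_SENTINELS = ("", "NA", "NaN", ".")


@dataclass(frozen=True)
class VariableSpec:
    """Description of a single raw cohort column.

    Parameters
    ----------
    name:
        Column identifier in the raw table.
    kind:
        Semantic kind: ``continuous``, ``ordinal``, ``binary`` or ``nominal``.
    direction:
        Risk direction: +1 (higher signal = higher risk), -1 (protective),
        or 0 (excluded from the risk index but kept as a model feature).
    valid_range:
        Inclusive (low, high) plausibility bounds; continuous only.
    codes:
        Mapping from raw survey code to encoded value (ordinal/binary) or to
        a level label (nominal).  Ordinal encodings must be consecutive
        integers; binary encodings must be {0, 1}.
    harmonized_name:
        Name of the signal after harmonization (defaults to ``name``).
    source_tag:
        Dataset of origin (free text, e.g. ``"nhanes"``).
    sentinels:
        Extra refusal/don't-know codes treated as missing for this variable.
    """

    name: str
    kind: str
    direction: int = 1
    valid_range: tuple[float, float] | None = None
    codes: Mapping[Any, Any] | None = None
    harmonized_name: str | None = None
    source_tag: str = ""
    sentinels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown semantic kind {self.kind!r} for {self.name!r}")
        if self.direction not in (-1, 0, 1):
            raise ValueError(f"risk direction of {self.name!r} must be -1, 0 or +1")
        if self.kind == "continuous":
            if self.valid_range is None:
                raise ValueError(f"continuous variable {self.name!r} needs valid_range")
            lo, hi = self.valid_range
            import math

            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(
                    f"valid_range of {self.name!r} must be finite with lower < upper"
                )
        else:
            if not self.codes:
                raise ValueError(f"{self.kind} variable {self.name!r} needs codes")
            if self.kind == "binary":
                enc = sorted(set(self.codes.values()))
                if enc not in ([0], [1], [0, 1]):
                    raise ValueError(
                        f"binary variable {self.name!r} must encode to 0/1"
                    )
            if self.kind == "ordinal":
                enc = sorted(set(self.codes.values()))
                if any(int(v) != v for v in enc) or enc != list(
                    range(int(enc[0]), int(enc[0]) + len(enc))
                ):
                    raise ValueError(
                        f"ordinal variable {self.name!r} must encode to consecutive integers"
                    )

    @property
    def target_name(self) -> str:
        return self.harmonized_name or self.name


@dataclass
class VariableManifest:
    """An ordered collection of :class:`VariableSpec` entries."""

    entries: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for spec in self.entries:
            if spec.target_name in seen:
                raise ValueError(
                    f"duplicate harmonized name {spec.target_name!r} in manifest"
                )
            seen.add(spec.target_name)

    def __iter__(self) -> Iterable[VariableSpec]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [s.name for s in self.entries]

    def get(self, name: str) -> VariableSpec:
        for spec in self.entries:
            if spec.name == name or spec.target_name == name:
                return spec
        raise KeyError(name)

    def directions(self) -> dict[str, int]:
        """Harmonized-name -> risk direction map."""
        return {s.target_name: s.direction for s in self.entries}

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        out = []
        for s in self.entries:
            d: dict[str, Any] = {
                "name": s.name,
                "kind": s.kind,
                "direction": s.direction,
                "harmonized_name": s.target_name,
                "source": s.source_tag,
            }
            if s.valid_range is not None:
                d["range"] = list(s.valid_range)
            if s.codes is not None:
                d["codes"] = dict(s.codes)
            if s.sentinels:
                d["sentinels"] = list(s.sentinels)
            out.append(d)
        return {"variables": out}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "VariableManifest":
        entries = []
        for d in payload["variables"]:
            entries.append(
                VariableSpec(
                    name=str(d["name"]),
                    kind=d["kind"],
                    direction=int(d.get("direction", 1)),
                    valid_range=tuple(d["range"]) if "range" in d else None,
                    codes=d.get("codes"),
                    harmonized_name=d.get("harmonized_name"),
                    source_tag=d.get("source", ""),
                    sentinels=tuple(str(x) for x in d.get("sentinels", ())),
                )
            )
        return cls(entries)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableManifest":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
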