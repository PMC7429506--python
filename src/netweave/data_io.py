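"""Reading interaction records and building weekly bipartite networks.

Input is a long-format table of plant-pollinator interaction observations
(season, week, plant, pollinator, count).  Records are aggregated into one
weighted bipartite network per sampled week, where an edge weight is the
total number of interaction events observed between that species pair in
that week.  Binary (qualitative) networks set every weight to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

PLANT = "plant"
POLLINATOR = "pollinator"

DEFAULT_COLUMNS = {
    "season": "season",
    "week": "week",
    "plant": "plant",
    "pollinator": "pollinator",
    "count": "count",
}


class ConfigurationError(ValueError):
    """A required column or configuration entry is missing."""


class ValidationError(ValueError):
    """Input rows violate the record invariants."""


@dataclass(frozen=True)
class InteractionRecord:
    """One observation: ``count`` interaction events between a plant and a
    pollinator in a given week of a season."""

    season: str
    week: int
    plant: str
    pollinator: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        if self.week < 1:
            raise ValidationError(f"week must be >= 1, got {self.week}")
        if not self.plant or not self.pollinator:
            raise ValidationError("taxon labels must be non-empty")


@dataclass(frozen=True)
class WeeklyNetwork:
    """One week's weighted bipartite plant-pollinator network.

    ``edges`` maps ``(plant, pollinator)`` to a positive weight.  Every node
    is incident to at least one edge by construction (species appear in a
    week only if they interacted that week).
    """

    season: str
    week: int
    edges: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (p, a), w in self.edges.items():
            if w <= 0:
                raise ValidationError(f"edge ({p}, {a}) has non-positive weight {w}")

    @property
    def plants(self) -> tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.edges}))

    @property
    def pollinators(self) -> tuple[str, ...]:
        return tuple(sorted({a for _, a in self.edges}))

    @property
    def species(self) -> tuple[str, ...]:
        return self.plants + self.pollinators

    def guild_of(self, sp: str) -> str:
        if sp in set(self.plants):
            return PLANT
        if sp in set(self.pollinators):
            return POLLINATOR
        raise KeyError(sp)

    def neighbors(self, sp: str) -> tuple[str, ...]:
        out = []
        for (p, a) in self.edges:
            if p == sp:
                out.append(a)
            elif a == sp:
                out.append(p)
        return tuple(sorted(out))

    @property
    def n_species(self) -> int:
        return len(self.plants) + len(self.pollinators)

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    @property
    def is_binary(self) -> bool:
        return all(w == 1 for w in self.edges.values())

    @property
    def id(self) -> tuple[str, int]:
        return (self.season, self.week)


@dataclass(frozen=True)
class NetworkSeries:
    """Ordered weekly networks of one sampling season.

    ``W`` is the number of *sampled* weeks (the length of the sequence);
    relative time in the transition model is week position divided by W.
    """

    season: str
    networks: tuple[WeeklyNetwork, ...]

    def __post_init__(self) -> None:
        weeks = [n.week for n in self.networks]
        if weeks != sorted(weeks) or len(set(weeks)) != len(weeks):
            raise ValidationError("weeks must be strictly increasing")

    @property
    def W(self) -> int:
        return len(self.networks)

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(n.week for n in self.networks)

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)


def load_records(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[InteractionRecord]:
    """Parse a delimited text file of interaction records.

    ``columns`` maps the canonical field names (season, week, plant,
    pollinator, count) to the column names used in the file.  Extra columns
    are ignored.  Delimiter is sniffed from the extension unless given.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records: list[InteractionRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header line
        try:
            records.append(
                InteractionRecord(
                    season=str(row[cols["season"]]),
                    week=int(row[cols["week"]]),
                    plant=str(row[cols["plant"]]),
                    pollinator=str(row[cols["pollinator"]]),
                    count=int(row[cols["count"]]),
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed row(s): " + "; ".join(problems))
    return records


def load_flower_counts(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Optional per-week flower counts for plants: a table with season,
    week, plant, flower_count columns, used as the plant abundance measure
    in the degree-abundance regression."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    required = ["season", "week", "plant", "flower_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing column(s) {missing}")
    if (df["flower_count"] < 0).any():
        raise ValidationError(f"{path}: negative flower counts")
    return df[required]


def aggregate_weekly(records: Sequence[InteractionRecord]) -> dict[str, NetworkSeries]:
    """Aggregate records into weekly weighted networks, one series per season.

    The weight of edge (plant, pollinator) in a given week is the sum of the
    counts of matching records.  Weeks with no records are not padded.
    """
    if not records:
        raise ValidationError("no records to aggregate")
    acc: dict[str, dict[int, dict[tuple[str, str], int]]] = {}
    for r in records:
        acc.setdefault(r.season, {}).setdefault(r.week, {})
        key = (r.plant, r.pollinator)
        acc[r.season][r.week][key] = acc[r.season][r.week].get(key, 0) + r.count
    out: dict[str, NetworkSeries] = {}
    for season in sorted(acc):
        nets = tuple(
            WeeklyNetwork(season=season, week=w, edges=dict(acc[season][w]))
            for w in sorted(acc[season])
        )
        out[season] = NetworkSeries(season=season, networks=nets)
    return out


def to_binary(net: WeeklyNetwork) -> WeeklyNetwork:
    """Return the qualitative counterpart: same topology, all weights 1."""
    return replace(net, edges={e: 1 for e in net.edges})


def series_to_frame(series_by_season: Mapping[str, NetworkSeries]) -> pd.DataFrame:
    """Export all weekly edge lists as one long DataFrame."""
    rows = []
    for season, series in series_by_season.items():
        for net in series:
            for (p, a), w in sorted(net.edges.items()):
                rows.append(
                    {"season": season, "week": net.week, "plant": p,
                     "pollinator": a, "weight": w}
                )
    return pd.DataFrame(rows, columns=["season", "week", "plant", "pollinator", "weight"])


def write_edge_lists(series_by_season: Mapping[str, NetworkSeries], path: str | Path) -> None:
    series_to_frame(series_by_season).to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[InteractionRecord]:
    """Build records from an in-memory long-format DataFrame (season, week,
    plant, pollinator, count/weight)."""
    count_col = "count" if "count" in df.columns else "weight"
    return [
        InteractionRecord(str(r.season), int(r.week), str(r.plant),
                          str(r.pollinator), int(getattr(r, count_col)))
        for r in df.itertuples(index=False)
    ]


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline with one global seed.

    Loadable from a YAML file; any entry may be overridden from the CLI.
    """

    seed: int = 0
    binary: bool = False
    motif_min_size: int = 3
    motif_max_size: int = 5
    role_normalization: str = "none"          # none | unit_sum | zscore
    weight_combine: str = "mean"              # mean | sum | geometric_mean
    n_alignments: int = 100
    unpaired_penalty: float = 1.0
    anneal_t0: float = 1.0
    anneal_cooling: float = 0.995
    anneal_sweeps: int = 500
    quality_weighting: str = "frequency_x_correlation"  # or: frequency
    walktrap_steps: int = 4
    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config entries: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
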