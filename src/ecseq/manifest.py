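"""Sample manifest: which library belongs to which individual, time point, replicate.

The study design this models is longitudinal with technical replication:
each individual contributes samples at two time points, each prepared as two
independent sequencing libraries (replicates A and B).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

COLUMNS = ["library_id", "individual_id", "timepoint", "replicate"]


@dataclass(frozen=True)
class LibraryInfo:
    library_id: str
    individual_id: str
    timepoint: int
    replicate: str


class SampleManifest:
    """Library -> (individual, time point, replicate) mapping with validation."""

    def __init__(self, rows: list[LibraryInfo]):
        seen: dict[str, LibraryInfo] = {}
        per_group: dict[tuple[str, int], set[str]] = {}
        for row in rows:
            if row.library_id in seen:
                raise ConfigurationError(f"duplicate library id {row.library_id!r}")
            if row.timepoint not in (1, 2):
                raise ConfigurationError(
                    f"timepoint must be 1 or 2, got {row.timepoint!r} for {row.library_id!r}")
            reps = per_group.setdefault((row.individual_id, row.timepoint), set())
            if row.replicate in reps:
                raise ConfigurationError(
                    f"duplicate replicate {row.replicate!r} for "
                    f"({row.individual_id}, timepoint {row.timepoint})")
            if len(reps) >= 2:
                raise ConfigurationError(
                    f"more than two replicates for ({row.individual_id}, {row.timepoint})")
            reps.add(row.replicate)
            seen[row.library_id] = row
        self._rows = {r.library_id: r for r in rows}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "individual_id": str,
                                                "replicate": str})
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"manifest missing columns: {sorted(missing)}")
        return cls([LibraryInfo(r.library_id, r.individual_id, int(r.timepoint), r.replicate)
                    for r in df.itertuples()])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.library_id, r.individual_id, r.timepoint, r.replicate)
             for r in self._rows.values()],
            columns=COLUMNS)

    # -- lookups -----------------------------------------------------------
    def __contains__(self, library_id: str) -> bool:
        return library_id in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def __getitem__(self, library_id: str) -> LibraryInfo:
        try:
            return self._rows[library_id]
        except KeyError:
            raise ConfigurationError(f"library {library_id!r} absent from manifest") from None

    @property
    def library_ids(self) -> list[str]:
        return list(self._rows)

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for r in self._rows.values():
            if r.individual_id not in out:
                out.append(r.individual_id)
        return out

    def libraries_of(self, individual_id: str, timepoint: int | None = None) -> list[str]:
        return [r.library_id for r in self._rows.values()
                if r.individual_id == individual_id
                and (timepoint is None or r.timepoint == timepoint)]

    def other_individuals_libraries(self, individual_id: str) -> list[str]:
        """Libraries from every individual except ``individual_id``."""
        return [r.library_id for r in self._rows.values()
                if r.individual_id != individual_id]
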