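"""Study design: subjects, diagnostic groups, clinical scores, analysis seed."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["StudyDesign", "GROUPS", "read_subject_table", "write_subject_table"]

GROUPS = ("HC", "MCI", "AD")


@dataclass
class StudyDesign:
    """Subject ids, group labels, clinical scores and analysis parameters.

    ``params`` holds whatever analysis configuration should travel with the
    design (permutation count, TFCE exponents, ...), so that one object fully
    determines a reproducible run.
    """

    subject_ids: tuple[str, ...]
    group_of: dict[str, str]
    cdr: dict[str, float] = field(default_factory=dict)
    mmse: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in design")
        missing = [s for s in self.subject_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"subjects without group label: {missing[:5]}")

    def subjects_in(self, group: str) -> list[str]:
        return [s for s in self.subject_ids if self.group_of[s] == group]

    def indices_in(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.subject_ids) if self.group_of[s] == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.subject_ids:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        return seen

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": list(self.subject_ids),
                "group": [self.group_of[s] for s in self.subject_ids],
                "cdr": [self.cdr.get(s, float("nan")) for s in self.subject_ids],
                "mmse": [self.mmse.get(s, float("nan")) for s in self.subject_ids],
            }
        )


def write_subject_table(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_subject_table(path: str | Path, seed: int = 0) -> StudyDesign:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subject table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"subject table must have columns {sorted(required)}")
    return StudyDesign(
        subject_ids=tuple(df["subject_id"]),
        group_of=dict(zip(df["subject_id"], df["group"])),
        cdr=dict(zip(df["subject_id"], df["cdr"])) if "cdr" in df else {},
        mmse=dict(zip(df["subject_id"], df["mmse"])) if "mmse" in df else {},
        seed=seed,
    )
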