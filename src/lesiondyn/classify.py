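"""Rule-based organ classification of tumor lesions.

Each lesion is assigned to one organ class by case-insensitive keyword
matching on the free-text location recorded in the case report form.
Non-metastatic lesions go to the reserved class "Primary lesions"
regardless of location; lesions with empty or unmatched location text go
to "Unclassified lesions".  Classes with few patients can afterwards be
merged into a pooled "Other" class, keeping the three main metastatic
sites (liver, lung, lymph node) intact.

The shipped default ruleset is a reconstruction of a typical keyword file
for metastatic colorectal cancer and is meant to be edited: load/save it
as YAML and adjust the keywords to the wording of your own dataset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .trial_data import LesionSeries

PRIMARY_CLASS = "Primary lesions"
UNCLASSIFIED_CLASS = "Unclassified lesions"
OTHER_CLASS = "Other"
MAIN_CLASSES = ("Liver", "Lung", "Lymph node")

_DEFAULT_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Liver", ("liver", "hepatic", "hepato")),
    ("Lung", ("lung", "pulmonary", "pulmon")),
    ("Lymph node", ("lymph", "node", "nodal", "adenopathy")),
    ("Other respiratory organs",
     ("pleura", "pleural", "mediastin", "bronch", "trachea")),
    ("Other digestive organs",
     ("periton", "pancrea", "spleen", "splen", "stomach", "gastric",
      "omentum", "bowel", "esophag", "duoden", "mesenter")),
    ("Other specified organs",
     ("adrenal", "kidney", "renal", "ovar", "uter", "bladder", "bone",
      "skin", "muscle", "soft tissue", "abdominal wall", "pelvi", "brain")),
)


def normalize_text(text: str) -> str:
    """Uppercase and strip punctuation; the matching dialect is substring
    search on this normalized form (no stemming)."""
    return re.sub(r"[^A-Z0-9]+", " ", str(text).upper()).strip()


@dataclass(frozen=True)
class ClassRuleset:
    """Ordered (class name, keywords) rules; first match wins.

    The reserved classes "Primary lesions" and "Unclassified lesions" are
    implicit and must not carry keyword rules.
    """

    rules: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.rules]
        if len(names) != len(set(names)):
            raise ValueError("class names must be unique")
        for name, kws in self.rules:
            if name in (PRIMARY_CLASS, UNCLASSIFIED_CLASS):
                raise ValueError(f"{name!r} is reserved and takes no keywords")
            if not kws or any(not str(k).strip() for k in kws):
                raise ValueError(f"class {name!r} needs non-empty keywords")

    @property
    def class_names(self) -> list[str]:
        return [name for name, _ in self.rules] + [PRIMARY_CLASS, UNCLASSIFIED_CLASS]

    @classmethod
    def default(cls) -> "ClassRuleset":
        return cls(_DEFAULT_RULES)

    @classmethod
    def from_yaml(cls, path) -> "ClassRuleset":
        """Load a ruleset from YAML: a list of one-key mappings
        ``{class name: [keyword, ...]}`` preserving order."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValueError("ruleset YAML must be a list of {class: [keywords]}")
        rules = []
        for entry in raw:
            if not isinstance(entry, Mapping) or len(entry) != 1:
                raise ValueError(f"bad ruleset entry: {entry!r}")
            (name, kws), = entry.items()
            rules.append((str(name), tuple(str(k) for k in kws)))
        return cls(tuple(rules))

    def to_yaml(self, path) -> None:
        data = [{name: list(kws)} for name, kws in self.rules]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class ClassifiedLesion:
    patient_id: str
    lesion_id: str
    class_name: str
    matched_keyword: str | None = None


def classify_lesion(patient_id: str, lesion_id: str, organ_text: str,
                    lesion_type: str, ruleset: ClassRuleset) -> ClassifiedLesion:
    """Assign one lesion to an organ class.

    Priority: primary lesion type first (class defined by type, not
    location), then the first ruleset class whose keyword occurs in the
    normalized location text, else "Unclassified lesions".
    """
    if lesion_type == "primary":
        return ClassifiedLesion(patient_id, lesion_id, PRIMARY_CLASS)
    text = normalize_text(organ_text)
    if text:
        for name, kws in ruleset.rules:
            for kw in kws:
                if normalize_text(kw) in text:
                    return ClassifiedLesion(patient_id, lesion_id, name, kw)
    return ClassifiedLesion(patient_id, lesion_id, UNCLASSIFIED_CLASS)


def classify_all(series_by_patient: Mapping[str, Mapping[str, LesionSeries]],
                 ruleset: ClassRuleset | None = None,
                 ) -> dict[str, dict[str, ClassifiedLesion]]:
    """Classify every lesion series; returns {patient: {lesion: classified}}."""
    ruleset = ruleset or ClassRuleset.default()
    out: dict[str, dict[str, ClassifiedLesion]] = {}
    for pid, lesions in series_by_patient.items():
        out[pid] = {
            lid: classify_lesion(pid, lid, s.organ_text, s.lesion_type, ruleset)
            for lid, s in lesions.items()
        }
    return out


@dataclass
class MergeReport:
    min_patients: int
    merged_classes: dict[str, int]  # class -> patient count before merging
    kept_classes: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "min_patients": self.min_patients,
            "merged_classes": dict(self.merged_classes),
            "kept_classes": dict(self.kept_classes),
        }


def patients_per_class(classified: Mapping[str, Mapping[str, ClassifiedLesion]],
                       ) -> dict[str, int]:
    """Distinct patients with at least one lesion in each class."""
    patients: dict[str, set[str]] = {}
    for pid, lesions in classified.items():
        for c in lesions.values():
            patients.setdefault(c.class_name, set()).add(pid)
    return {name: len(pids) for name, pids in patients.items()}


def merge_rare_classes(classified: Mapping[str, Mapping[str, ClassifiedLesion]],
                       min_patients: int = 30,
                       ) -> tuple[dict[str, dict[str, ClassifiedLesion]], MergeReport]:
    """Pool sparsely populated classes into "Other".

    Classes (other than the always-reported main classes Liver, Lung and
    Lymph node) with strictly fewer than ``min_patients`` distinct patients
    are relabeled "Other".  Lesion counts are unchanged; only labels move.
    """
    counts = patients_per_class(classified)
    merged = {name: n for name, n in counts.items()
              if name not in MAIN_CLASSES and n < min_patients}
    kept = {name: n for name, n in counts.items() if name not in merged}

    out: dict[str, dict[str, ClassifiedLesion]] = {}
    for pid, lesions in classified.items():
        out[pid] = {}
        for lid, c in lesions.items():
            if c.class_name in merged:
                out[pid][lid] = ClassifiedLesion(c.patient_id, c.lesion_id,
                                                 OTHER_CLASS, c.matched_keyword)
            else:
                out[pid][lid] = c
    return out, MergeReport(min_patients, merged, kept)


def class_summary(classified: Mapping[str, Mapping[str, ClassifiedLesion]],
                  subsets: Mapping[str, Iterable[str]] | None = None,
                  ) -> pd.DataFrame:
    """Per-class cTL and iTL counts for one or more patient subsets.

    cTL = number of distinct patients having >= 1 lesion of the class (one
    class-related target lesion per patient and organ); iTL = number of
    individual lesions.  Rows are classes plus a "Total" row; columns are a
    (subset, {cTL, iTL}) MultiIndex.
    """
    if subsets is None:
        subsets = {"ALL": list(classified)}
    subset_sets = {name: set(pids) for name, pids in subsets.items()}

    class_order: list[str] = []
    for pid in classified:
        for c in classified[pid].values():
            if c.class_name not in class_order:
                class_order.append(c.class_name)
    ordered = [c for c in MAIN_CLASSES if c in class_order]
    ordered += sorted(c for c in class_order
                      if c not in MAIN_CLASSES and c != OTHER_CLASS)
    if OTHER_CLASS in class_order:
        ordered.append(OTHER_CLASS)

    columns = pd.MultiIndex.from_product([list(subsets), ["cTL", "iTL"]])
    table = pd.DataFrame(0, index=ordered + ["Total"], columns=columns)
    for sub_name, pids in subset_sets.items():
        ctl: dict[str, set[str]] = {}
        itl: dict[str, int] = {}
        total_patients: set[str] = set()
        total_lesions = 0
        for pid, lesions in classified.items():
            if pid not in pids:
                continue
            for c in lesions.values():
                ctl.setdefault(c.class_name, set()).add(pid)
                itl[c.class_name] = itl.get(c.class_name, 0) + 1
                total_patients.add(pid)
                total_lesions += 1
        for name in ordered:
            table.loc[name, (sub_name, "cTL")] = len(ctl.get(name, ()))
            table.loc[name, (sub_name, "iTL")] = itl.get(name, 0)
        # total cTLs = sum over classes (a patient counts once per class)
        table.loc["Total", (sub_name, "cTL")] = sum(len(s) for s in ctl.values())
        table.loc["Total", (sub_name, "iTL")] = total_lesions
    return table


def format_class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Render a class summary as "cTL (iTL)" strings, one column per subset."""
    subsets = table.columns.get_level_values(0).unique()
    out = pd.DataFrame(index=table.index)
    for s in subsets:
        out[s] = [f"{table.loc[i, (s, 'cTL')]} ({table.loc[i, (s, 'iTL')]})"
                  for i in table.index]
    return out
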