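"""Drug design specifications and multiple-molecule drug assembly.

Given disease biomarkers annotated with their dysregulation direction
((+) abnormal overexpression, (-) abnormal low expression) and per-drug
profiles — a signed L1000-style regulation ability per biomarker, a
PRISM-style sensitivity score (lower = potent at lower dose) and an LD50
toxicity value (log-scaled mol/kg; lower = more toxic) — the filter keeps
drugs whose regulation *reverses* the biomarker's dysregulation
(sign-consistency), optionally applies toxicity/sensitivity cutoffs, and
assembles a minimal set of drugs jointly covering every biomarker by greedy
set cover.  Sign-consistency is the only hard criterion by default;
toxicity and sensitivity act as ranking keys and optional cutoffs, since a
useful multi-target drug may sit anywhere on those scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("gwgen")

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class BiomarkerSpec:
    """A drug target with its dysregulation direction relative to control."""

    name: str
    direction: str  # '+' abnormal overexpression, '-' abnormal low expression

    def __post_init__(self) -> None:
        if self.direction not in {"+", "-"}:
            raise ValueError(f"direction must be '+' or '-', got {self.direction!r}")


@dataclass
class DrugProfile:
    """One drug's per-biomarker regulation abilities plus toxicity/sensitivity."""

    name: str
    regulation: dict[str, float]  # biomarker -> signed regulation ability
    sensitivity: float
    toxicity: float  # LD50, log-scaled mol/kg; lower value = more toxic


def sign_consistent(regulation: float, direction: str) -> bool:
    """True iff the drug's regulation reverses the biomarker's dysregulation.

    An overexpressed (+) biomarker needs down-regulation (< 0); an
    underexpressed (-) biomarker needs up-regulation (> 0).  Zero regulation
    reverses nothing.
    """
    if direction == "+":
        return regulation < 0
    if direction == "-":
        return regulation > 0
    raise ValueError(f"direction must be '+' or '-', got {direction!r}")


@dataclass
class FilterConfig:
    min_ld50: float | None = None  # toxicity floor: reject drugs more toxic than this
    max_sensitivity: float | None = None  # sensitivity ceiling: reject weaker drugs


def filter_candidates(
    profiles: list[DrugProfile],
    biomarkers: list[BiomarkerSpec],
    config: FilterConfig | None = None,
) -> dict[str, list[tuple[str, float]]]:
    """Per-biomarker admissible drugs, ranked by |regulation| descending.

    A drug is admissible for a biomarker when it has a measured regulation
    ability there, the sign reverses the dysregulation, and it passes any
    configured toxicity/sensitivity cutoffs.  Biomarkers with no admissible
    drug are reported in the log, not fatal.
    """
    config = config or FilterConfig()
    out: dict[str, list[tuple[str, float]]] = {}
    for marker in biomarkers:
        hits = []
        for prof in profiles:
            if marker.name not in prof.regulation:
                continue
            reg = prof.regulation[marker.name]
            if not sign_consistent(reg, marker.direction):
                continue
            if config.min_ld50 is not None and prof.toxicity < config.min_ld50:
                continue
            if config.max_sensitivity is not None and prof.sensitivity > config.max_sensitivity:
                continue
            hits.append((prof.name, reg))
        hits.sort(key=lambda t: (-abs(t[1]), t[0]))
        if not hits:
            logger.warning("biomarker %s: no admissible drug", marker.name)
        out[marker.name] = hits
    return out


@dataclass
class MultiMoleculeDrug:
    """A drug combination covering every biomarker with reversing regulation."""

    drugs: list[str]
    assignments: dict[str, dict[str, float]]  # drug -> {biomarker: regulation}
    toxicity: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)

    def covered_biomarkers(self) -> set[str]:
        return {m for cov in self.assignments.values() for m in cov}

    def to_table(self, biomarkers: list[BiomarkerSpec]) -> pd.DataFrame:
        """Check-mark layout: one row per drug, matched regulation values as marks."""
        rows = []
        for drug in self.drugs:
            row: dict[str, object] = {"drug": drug}
            for marker in biomarkers:
                val = self.assignments[drug].get(marker.name)
                row[marker.name] = "" if val is None else f"({val:+.4f})"
            row["toxicity_ld50"] = self.toxicity.get(drug)
            row["sensitivity"] = self.sensitivity.get(drug)
            rows.append(row)
        return pd.DataFrame(rows)


def select_multi_drug(
    admissible: dict[str, list[tuple[str, float]]],
    profiles: list[DrugProfile],
) -> MultiMoleculeDrug:
    """Greedy weighted set cover over the admissible (drug, biomarker) pairs.

    Repeatedly picks the drug covering the most still-uncovered biomarkers;
    ties are broken toward the drug admissible for more biomarkers overall
    (multi-target economy), then larger mean |regulation| over the newly
    covered biomarkers, then more-favorable (lower) sensitivity, then name.
    The returned assignments are *all* admissible pairs of the selected
    drugs, not only those that were uncovered at pick time.
    """
    gaps = [m for m, hits in admissible.items() if not hits]
    if gaps:
        raise ValueError(f"biomarkers with no admissible drug: {sorted(gaps)}")
    prof_map = {p.name: p for p in profiles}
    coverage: dict[str, dict[str, float]] = {}
    for marker, hits in admissible.items():
        for drug, reg in hits:
            coverage.setdefault(drug, {})[marker] = reg

    uncovered = set(admissible)
    selected: list[str] = []
    while uncovered:
        best = None
        for drug, cov in coverage.items():
            if drug in selected:
                continue
            new = uncovered & set(cov)
            if not new:
                continue
            mean_reg = sum(abs(cov[m]) for m in new) / len(new)
            sens = prof_map[drug].sensitivity if drug in prof_map else 0.0
            key = (-len(new), -len(cov), -mean_reg, sens, drug)
            if best is None or key < best[0]:
                best = (key, drug, new)
        if best is None:
            raise ValueError(f"biomarkers uncoverable by remaining drugs: {sorted(uncovered)}")
        _, drug, new = best
        selected.append(drug)
        uncovered -= new

    return MultiMoleculeDrug(
        drugs=selected,
        assignments={d: dict(sorted(coverage[d].items())) for d in selected},
        toxicity={d: prof_map[d].toxicity for d in selected if d in prof_map},
        sensitivity={d: prof_map[d].sensitivity for d in selected if d in prof_map},
    )


# -- table IO and the bundled worked example ------------------------------------


def load_biomarkers(path: str | Path) -> list[BiomarkerSpec]:
    """``biomarkers.tsv`` columns: name, direction ('+'/'-')."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [BiomarkerSpec(r.name, r.direction) for r in df.itertuples(index=False)]


def load_drug_profiles(path: str | Path) -> list[DrugProfile]:
    """``drug_profiles.tsv`` columns: drug, biomarker, regulation, sensitivity, toxicity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles: dict[str, DrugProfile] = {}
    for r in df.itertuples(index=False):
        prof = profiles.get(r.drug)
        if prof is None:
            prof = DrugProfile(
                name=r.drug, regulation={}, sensitivity=float(r.sensitivity),
                toxicity=float(r.toxicity),
            )
            profiles[r.drug] = prof
        prof.regulation[r.biomarker] = float(r.regulation)
    return [profiles[name] for name in sorted(profiles)]


def load_oscc_example() -> tuple[list[DrugProfile], list[BiomarkerSpec]]:
    """Bundled OSCC worked example: candidate drugs screened against the four
    transcription-factor biomarkers HES1, TCF, NF-kB and SP1 with published
    L1000 regulation abilities, PRISM sensitivities and DrugBank LD50 values."""
    profiles = load_drug_profiles(_DATA_DIR / "oscc_candidate_drugs.tsv")
    biomarkers = load_biomarkers(_DATA_DIR / "oscc_biomarkers.tsv")
    return profiles, biomarkers
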