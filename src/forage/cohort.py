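"""Synthetic cohorts: labeled multi-subject, multi-session datasets.

Generates the study-design structure — wild-type (WT) and heterozygous
(HET) subjects balanced over sex, each run through a training curriculum
and the full foraging task — using the agents as behaving animals.  A
genotype effect can be injected as a documented multiplicative perturbation
of one agent parameter; the default effect size is zero, the null under
which the study reported no genotype differences, so WT and HET behavior
is exchangeable by construction and the cohorts calibrate the type-I error
of the comparison pipeline.

Subject-session seeds are derived deterministically from the master seed
via ``numpy.random.SeedSequence`` spawning, so a cohort is a pure function
of its spec.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import task_engine as te
from .agents import make_agent
from .task_engine import InvalidParameterError, Session, TaskConfig, get_preset

GENOTYPES = ("WT", "HET")
SEXES = ("M", "F")

DEFAULT_AGENT_SPEC = {"type": "q_softmax",
                      "params": {"alpha": 0.2, "beta": 3.0}}


@dataclass
class CohortSpec:
    """Design of one synthetic cohort.

    ``n_per_cell`` subjects are generated per genotype-by-sex cell (the
    default of 12 gives 24 per genotype, the scale of the study);
    ``curriculum`` is the ordered list of task presets (or TaskConfigs)
    every subject runs, ``sessions_per_subject`` sessions each.  The
    genotype effect multiplies ``effect_param`` of the HET agents by
    ``1 - effect_size``; ``effect_size=0`` (default) leaves the genotypes
    identically parameterized.
    """

    n_per_cell: int = 12
    sessions_per_subject: int = 1
    curriculum: Sequence[Union[str, TaskConfig]] = ("full_15_60",)
    agent_spec: Dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_AGENT_SPEC))
    agent_spec_by_genotype: Optional[Dict[str, Dict]] = None
    effect_size: float = 0.0
    effect_param: str = "alpha"
    seizure_fraction_het: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise InvalidParameterError("n_per_cell must be >= 1")
        if self.sessions_per_subject < 1:
            raise InvalidParameterError("sessions_per_subject must be >= 1")
        if not self.curriculum:
            raise InvalidParameterError("curriculum must be non-empty")
        if self.agent_spec_by_genotype is not None and self.effect_size != 0:
            raise InvalidParameterError(
                "give either explicit per-genotype agent specs or an "
                "effect_size perturbation, not both")

    def resolved_configs(self) -> List[TaskConfig]:
        return [c if isinstance(c, TaskConfig) else get_preset(c)
                for c in self.curriculum]

    def agent_spec_for(self, genotype: str) -> Dict:
        if self.agent_spec_by_genotype is not None:
            return copy.deepcopy(self.agent_spec_by_genotype[genotype])
        spec = copy.deepcopy(self.agent_spec)
        if genotype == "HET" and self.effect_size != 0:
            params = spec.setdefault("params", {})
            if self.effect_param not in params:
                raise InvalidParameterError(
                    f"effect_param {self.effect_param!r} not in agent params")
            params[self.effect_param] *= (1.0 - self.effect_size)
        return spec


@dataclass
class Cohort:
    """Sessions grouped by labeled subjects; the unit of group comparison."""

    subjects: pd.DataFrame          # subject_id, genotype, sex, seizure_flag
    sessions: List[Session]
    master_seed: int = 0

    def sessions_for(self, genotype: Optional[str] = None,
                     variant: Optional[str] = None) -> List[Session]:
        meta = self.subjects.set_index("subject_id")
        out = []
        for s in self.sessions:
            if genotype is not None and meta.loc[s.subject_id, "genotype"] != genotype:
                continue
            if variant is not None and s.variant != variant:
                continue
            out.append(s)
        return out

    def equals(self, other: "Cohort") -> bool:
        """Content equality on the CSV-visible data (trials + labels)."""
        if not self.subjects.reset_index(drop=True).equals(
                other.subjects.reset_index(drop=True)):
            return False
        if len(self.sessions) != len(other.sessions):
            return False
        for a, b in zip(self.sessions, other.sessions):
            # variant is not part of the CSV schema, hence not compared
            if (a.subject_id, a.session_id, a.genotype, a.sex) != \
               (b.subject_id, b.session_id, b.genotype, b.sex):
                return False
            if a.block_boundaries != b.block_boundaries:
                return False
            if len(a.trials) != len(b.trials):
                return False
            for ta, tb in zip(a.trials, b.trials):
                if (ta.index, ta.block_index, ta.high_side, ta.choice,
                        ta.rewarded) != (tb.index, tb.block_index,
                                         tb.high_side, tb.choice, tb.rewarded):
                    return False
                for xa, xb in ((ta.iti_s, tb.iti_s),
                               (ta.nolick_duration_s, tb.nolick_duration_s)):
                    if (xa is None) != (xb is None):
                        return False
                    if xa is not None and abs(xa - xb) > 1e-9:
                        return False
        return True


def null_rejection_rate(n_replicates: int = 1000, n_per_cell: int = 4,
                        max_trials: int = 200, eps: float = 0.15,
                        base_seed: int = 1,
                        metrics: Sequence[str] = ("win_stay", "lose_switch"),
                        alpha: Optional[float] = None) -> float:
    """Family-wise type-I error of the genotype comparison under the null.

    Generates ``n_replicates`` cohorts with ``effect_size=0`` (so WT and
    HET agents are identically parameterized WSLS-with-lapse policies),
    runs the Bonferroni-corrected pairwise Mann-Whitney family over the
    per-subject ``metrics``, and returns the fraction of replicates with
    any adjusted p below ``alpha``.  Replicate r uses master seed
    ``base_seed + r``.
    """
    from .metrics import subject_metrics
    from .stats import ALPHA, compare_metric_tables

    if alpha is None:
        alpha = ALPHA
    config = get_preset("full_15_60", max_trials=max_trials)
    agent_spec = {"type": "wsls", "params": {"eps": eps}}
    rejections = 0
    for r in range(n_replicates):
        spec = CohortSpec(n_per_cell=n_per_cell, curriculum=(config,),
                          agent_spec=agent_spec, effect_size=0.0,
                          master_seed=base_seed + r)
        table = subject_metrics(generate_cohort(spec).sessions)
        report = compare_metric_tables(
            table[table.genotype == "WT"], table[table.genotype == "HET"],
            metrics=list(metrics), alpha=alpha)
        rejections += report["any_significant"]
    return rejections / n_replicates


def _session_seed(ss_state: np.ndarray) -> int:
    # keep recorded seeds in signed-int32 range
    return int(ss_state[0] % (2 ** 31))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate every subject of ``spec`` through its curriculum.

    One session per subject x curriculum-stage x session-index, with
    per-session RNGs spawned from ``master_seed`` so any sub-stream is
    reproducible independently of the others.
    """
    configs = spec.resolved_configs()
    root = np.random.SeedSequence(spec.master_seed)
    subj_rows = []
    sessions: List[Session] = []
    subject_index = 0
    flag_rng = np.random.default_rng(root.spawn(1)[0])
    for genotype in GENOTYPES:
        agent_spec = spec.agent_spec_for(genotype)
        for sex in SEXES:
            for i in range(spec.n_per_cell):
                sid = f"{genotype}_{sex}_{i:02d}"
                seizure = bool(
                    genotype == "HET"
                    and flag_rng.random() < spec.seizure_fraction_het)
                subj_rows.append({"subject_id": sid, "genotype": genotype,
                                  "sex": sex, "seizure_flag": seizure})
                session_counter = 0
                for stage, config in enumerate(configs):
                    for rep in range(spec.sessions_per_subject):
                        child = np.random.SeedSequence(
                            entropy=spec.master_seed,
                            spawn_key=(subject_index + 1, session_counter))
                        # session is a pure function of this integer seed
                        seed = _session_seed(child.generate_state(1))
                        agent = make_agent(agent_spec)
                        sess = te.run_session(
                            agent, config, subject_id=sid, genotype=genotype,
                            sex=sex, session_id=f"stage{stage}_rep{rep}",
                            seed=seed)
                        sessions.append(sess)
                        session_counter += 1
                subject_index += 1
    subjects = pd.DataFrame(subj_rows,
                            columns=["subject_id", "genotype", "sex",
                                     "seizure_flag"])
    return Cohort(subjects=subjects, sessions=sessions,
                  master_seed=spec.master_seed)
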