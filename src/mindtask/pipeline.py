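"""End-to-end glue: raw trials -> spatial filter -> PSD feature cohort.

For raw recordings the surface Laplacian is applied by default before
feature extraction; precomputed feature files bypass both stages and
enter the pipeline at the :class:`~mindtask.io_formats.SubjectSessions`
level.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .features import PSDConfig, extract_psd
from .io_formats import PSDFeatureMatrix, SubjectSessions, concat_matrices
from .spatial import surface_laplacian
from .synthetic import TrialRecord


def trials_to_sessions(
    trials: list[TrialRecord],
    psd_cfg: PSDConfig | None = None,
    laplacian: bool = True,
) -> list[SubjectSessions]:
    """Convert generated raw trials into per-subject feature sessions.

    Each trial is (optionally Laplacian-) filtered and windowed into PSD
    rows; rows of all trials of one session are stacked in trial order.
    Subject order follows first appearance in ``trials``.
    """
    psd_cfg = psd_cfg or PSDConfig()
    per_session: dict[tuple[str, str], list[PSDFeatureMatrix]] = defaultdict(list)
    subject_order: list[str] = []
    session_order: dict[str, list[str]] = defaultdict(list)
    for tr in trials:
        rec = tr.recording
        if laplacian:
            rec = surface_laplacian(rec, list(psd_cfg.channels))
        feats = extract_psd(
            rec, psd_cfg, subject_id=tr.subject_id, session_id=tr.session_id
        )
        per_session[(tr.subject_id, tr.session_id)].append(feats)
        if tr.subject_id not in subject_order:
            subject_order.append(tr.subject_id)
        if tr.session_id not in session_order[tr.subject_id]:
            session_order[tr.subject_id].append(tr.session_id)

    cohort = []
    for sid in subject_order:
        sessions = []
        for sess in session_order[sid]:
            m = concat_matrices(per_session[(sid, sess)])
            m.subject_id, m.session_id = sid, sess
            sessions.append(m)
        cohort.append(SubjectSessions(subject_id=sid, sessions=sessions))
    return cohort
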