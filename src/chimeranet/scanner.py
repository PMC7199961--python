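"""Full-transcript miRNA target prediction.

Pipeline per (miRNA, transcript) pair:

1. enumerate sliding-window candidate sites of length 110 - len(miRNA),
   so each candidate chimera is exactly 110 nt without padding;
2. compute each site's duplex MFE against the miRNA and keep sites at or
   below the energy threshold (default -20 kcal/mol) — long transcripts
   would otherwise accumulate false positives;
3. score surviving chimeras with the trained CNN;
4. aggregate by the maximum site score; the transcript-level call is True
   iff that maximum exceeds the decision threshold (default 0.5).

Transcripts shorter than the window length yield a single candidate whose
chimera is padded up to 110 nt with the anti-complementary pad used for
training positives (shared code path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import cnn_model, duplex_energy
from .chimera_builder import EncodedBatch, concatenate_chimera, encode_one_hot, pad_chimera
from .exceptions import ChimeranetError, ValidationError
from .sequence_io import CHIMERA_LENGTH, SequenceRecord

logger = logging.getLogger(__name__)

MIN_TRANSCRIPT_LENGTH = 8


@dataclass
class CandidateSite:
    """A window on the transcript, 0-based half-open coordinates."""

    transcript_id: str
    start: int
    end: int
    site_seq: str
    mfe: float = np.nan
    score: float | None = None

    def __post_init__(self):
        if self.end - self.start != len(self.site_seq):
            raise ValidationError("site coordinates do not match sequence length")


@dataclass
class ScanResult:
    mirna_id: str
    transcript_id: str
    sites: list[CandidateSite]  # MFE-surviving, scored sites
    n_candidates: int
    max_score: float
    call: bool

    @property
    def best_site(self) -> CandidateSite | None:
        if not self.sites:
            return None
        return max(self.sites, key=lambda s: s.score)


def enumerate_candidates(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    step: int = 5,
    *,
    min_transcript_length: int = MIN_TRANSCRIPT_LENGTH,
) -> list[CandidateSite]:
    """Sliding windows of length 110 - len(miRNA) at the given step, plus a
    terminal window flush with the transcript end; a transcript no longer
    than the window yields one whole-transcript candidate."""
    if step < 1:
        raise ValidationError("step must be >= 1")
    L = len(transcript.seq)
    if L < min_transcript_length:
        raise ValidationError(
            f"transcript {transcript.id} is {L} nt; minimum is {min_transcript_length}"
        )
    w = CHIMERA_LENGTH - len(mirna.seq)
    if w < 1:
        raise ValidationError(f"miRNA {mirna.id} leaves no room for a target site")
    if L <= w:
        return [CandidateSite(transcript.id, 0, L, transcript.seq)]
    starts = list(range(0, L - w + 1, step))
    if starts[-1] != L - w:
        starts.append(L - w)
    return [
        CandidateSite(transcript.id, s, s + w, transcript.seq[s : s + w])
        for s in starts
    ]


def scan_transcript(
    model: cnn_model.TrainedModel,
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    *,
    params: duplex_energy.NNParameterSet | None = None,
    mfe_threshold: float = -20.0,
    call_threshold: float = 0.5,
    step: int = 5,
    rng: np.random.Generator | None = None,
) -> ScanResult:
    """Score one (miRNA, transcript) pair; see the module docstring."""
    if params is None:
        params = duplex_energy.default_parameters()
    if rng is None:
        rng = np.random.default_rng(0)
    candidates = enumerate_candidates(mirna, transcript, step)
    n_candidates = len(candidates)
    survivors: list[CandidateSite] = []
    for cand in candidates:
        result = duplex_energy.duplex_mfe(mirna.seq, cand.site_seq, params)
        if result.mfe <= mfe_threshold:
            survivors.append(replace(cand, mfe=result.mfe))
    if not survivors:
        return ScanResult(mirna.id, transcript.id, [], n_candidates, 0.0, False)
    mats = []
    for cand in survivors:
        raw = concatenate_chimera(mirna, cand.site_seq)
        full = pad_chimera(raw, mirna.seq, rng) if len(raw) < CHIMERA_LENGTH else raw
        mats.append(encode_one_hot(full))
    batch = EncodedBatch(np.stack(mats), np.zeros(len(mats), dtype=np.int64))
    scores = cnn_model.predict(model, batch)
    scored = [replace(c, score=float(s)) for c, s in zip(survivors, scores)]
    max_score = float(scores.max())
    return ScanResult(
        mirna.id,
        transcript.id,
        scored,
        n_candidates,
        max_score,
        max_score > call_threshold,
    )


def scan_many(
    model: cnn_model.TrainedModel,
    mirnas: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    **kwargs,
) -> list[ScanResult]:
    """All (miRNA, transcript) pairs in deterministic order; per-pair
    failures are logged and skipped rather than aborting the batch."""
    results = []
    for mirna in mirnas:
        for transcript in transcripts:
            try:
                results.append(scan_transcript(model, mirna, transcript, **kwargs))
            except ChimeranetError as exc:
                logger.warning("skipping %s x %s: %s", mirna.id, transcript.id, exc)
    return results


def results_to_rows(results: Sequence[ScanResult]) -> list[dict]:
    """Flatten scan results for TSV output."""
    rows = []
    for r in results:
        best = r.best_site
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "transcript_id": r.transcript_id,
                "n_candidates": r.n_candidates,
                "n_survivors": len(r.sites),
                "best_site_start": best.start if best else -1,
                "best_site_end": best.end if best else -1,
                "best_mfe": best.mfe if best else float("nan"),
                "max_score": r.max_score,
                "call": r.call,
            }
        )
    return rows
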