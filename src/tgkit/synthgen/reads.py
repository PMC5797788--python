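"""Paired-end short-read simulator with per-base quality-driven errors.

Fragments are drawn per haplotype with uniform start positions and normal
insert sizes; each mate reads 150 bp from one fragment end (mate 2 on the
reverse strand).  Fragments shorter than the read length read through into
the library adapter at the 3' end.  Base qualities follow a per-cycle mean
profile with Gaussian scatter, and substitution errors are injected at the
Phred-implied rate.  No indel errors are simulated.

``params.coverage`` is the depth contributed by EACH listed haplotype, so a
diploid genome sequenced to 13.5x is simulated by listing both haplotype
copies with coverage 6.75 (the pipeline does exactly that).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..dna import _DECODE, encode
from ..readprep import DEFAULT_ADAPTER, ReadRecord


def default_quality_profile(read_len: int = 150) -> np.ndarray:
    """Per-cycle mean Phred quality: flat q37 with a mild 3' taper to q33."""
    prof = np.full(read_len, 37.0)
    tail = min(15, read_len)
    prof[-tail:] = np.linspace(37.0, 33.0, tail)
    return prof


@dataclass
class ReadSimParams:
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 13.5
    quality_profile: np.ndarray | None = None
    quality_sd: float = 3.0
    adapter: str = DEFAULT_ADAPTER
    error_scale: float = 1.0   # multiplies the Phred-implied error rate; 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 36:
            raise ValueError("read_len must be >= 36")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.quality_profile is None:
            self.quality_profile = default_quality_profile(self.read_len)
        self.quality_profile = np.asarray(self.quality_profile, dtype=float)
        if self.quality_profile.shape != (self.read_len,):
            raise ValueError("quality profile length must equal read_len")


def simulate_read_pairs(
    haplotypes: Sequence[tuple[str, str]],
    params: ReadSimParams | None = None,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """Simulate pairs from every haplotype; returns (mates1, mates2, truth).

    The truth table records, per pair, the source haplotype, the 1-based
    fragment start and the fragment length.  Deterministic for a fixed
    ``params.seed``.
    """
    params = params or ReadSimParams()
    if not haplotypes or any(len(s) == 0 for _, s in haplotypes):
        raise ValueError("empty haplotype set")
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    adapter_ext = np.concatenate(
        [encode(params.adapter), np.zeros(rl, dtype=np.uint8)]  # pad with 'A'
    )
    j = np.arange(rl)

    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    truth_rows: list[tuple[str, str, int, int]] = []
    pair_no = 0

    for hap_name, seq in haplotypes:
        codes = encode(seq)
        L = codes.size
        n = int(round(params.coverage * L / (2 * rl)))
        if n == 0:
            continue
        flen = np.clip(
            np.round(rng.normal(params.insert_mean, params.insert_sd, n)), 20, L
        ).astype(np.int64)
        start = (rng.random(n) * (L - flen + 1)).astype(np.int64)

        take = j[None, :] < np.minimum(flen, 10**9)[:, None]
        idx1 = np.minimum(start[:, None] + j[None, :], L - 1)
        ad_idx = np.clip(j[None, :] - flen[:, None], 0, adapter_ext.size - 1)
        m1 = np.where(take, codes[idx1], adapter_ext[ad_idx])
        idx2 = np.clip(start[:, None] + flen[:, None] - 1 - j[None, :], 0, L - 1)
        m2 = np.where(take, (3 - codes[idx2]).astype(np.uint8), adapter_ext[ad_idx])

        for m in (m1, m2):
            q = np.clip(
                np.round(
                    np.broadcast_to(params.quality_profile, m.shape)
                    + rng.normal(0.0, params.quality_sd, size=m.shape)
                ),
                2, 41,
            ).astype(np.int16)
            perr = params.error_scale * 10.0 ** (-q / 10.0)
            hit = rng.random(m.shape) < perr
            shift = rng.integers(1, 4, size=m.shape, dtype=np.uint8)
            m += np.where(hit, shift, 0).astype(np.uint8)
            m %= 4
            chars = _DECODE[m]
            is_first = m is m1
            for i in range(n):
                rec = ReadRecord(
                    f"p{pair_no + i}", chars[i].tobytes().decode("ascii"), q[i]
                )
                (reads1 if is_first else reads2).append(rec)
        for i in range(n):
            truth_rows.append((f"p{pair_no + i}", hap_name, int(start[i]) + 1, int(flen[i])))
        pair_no += n

    truth = pd.DataFrame(truth_rows, columns=["pair_id", "source", "frag_start", "frag_len"])
    return reads1, reads2, truth
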