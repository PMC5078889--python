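"""Per-sample substitution-class fractions as mutagen-exposure proxies.

Single-nucleotide variants collapse onto six pyrimidine-context classes
(C>A, C>G, C>T, T>A, T>C, T>G); purine-reference substitutions are
complemented (G>A becomes C>T).  The C>T fraction serves as the UV-exposure
proxy (cyclobutane-dimer mutagenesis in melanoma) and the C>A fraction as
the tobacco-smoking proxy (benzo[a]pyrene adducts in lung cancer).  These
are single-base proxies, not a full trinucleotide signature deconvolution;
precomputed per-sample fractions from an external signature analysis can be
supplied instead wherever a profile table is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .maf_io import Cohort, MutationRecord

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

UV_CLASS = "C>T"
SMOKING_CLASS = "C>A"


def substitution_class(ref: str, alt: str) -> Optional[str]:
    """Collapse a single-base substitution onto the pyrimidine strand.

    Returns None (not-a-SNV) for indels, multi-base or non-ACGT alleles, so
    callers simply skip such records.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SignatureProfile:
    """Six-class substitution spectrum of one sample.

    Fractions sum to 1 when the sample has at least one usable SNV; a sample
    with no SNVs gets all-zero fractions and ``undefined=True``.
    """

    sample_id: str
    n_snv: int
    fraction_by_class: dict[str, float]
    undefined: bool = False

    @property
    def uv_fraction(self) -> float:
        return self.fraction_by_class[UV_CLASS]

    @property
    def smoking_fraction(self) -> float:
        return self.fraction_by_class[SMOKING_CLASS]


def signature_profile(
    cohort: Cohort,
    records: Optional[Sequence[MutationRecord]] = None,
) -> list[SignatureProfile]:
    """Per-sample substitution-class fractions over SNVs only.

    Records without usable single-base ref/alt alleles are skipped (and do
    not enter ``n_snv``).  Every cohort sample receives a profile, including
    SNV-free samples (flagged undefined).
    """
    if records is None:
        records = cohort.records
    counts: dict[str, dict[str, int]] = {
        s: dict.fromkeys(SUBSTITUTION_CLASSES, 0) for s in cohort.samples
    }
    for rec in records:
        cls = substitution_class(rec.ref_allele, rec.alt_allele)
        if cls is None or rec.sample_id not in counts:
            continue
        counts[rec.sample_id][cls] += 1

    profiles = []
    for sample in sorted(counts):
        by_class = counts[sample]
        n = sum(by_class.values())
        if n == 0:
            fractions = dict.fromkeys(SUBSTITUTION_CLASSES, 0.0)
        else:
            fractions = {c: k / n for c, k in by_class.items()}
        profiles.append(
            SignatureProfile(
                sample_id=sample,
                n_snv=n,
                fraction_by_class=fractions,
                undefined=(n == 0),
            )
        )
    return profiles


def rank_by_load(
    cohort: Cohort,
    profiles: Sequence[SignatureProfile],
) -> pd.DataFrame:
    """Cohort table ranked by ascending ATML (ties by sample id).

    Columns: rank (1-based), sample_id, atml, uv_fraction, smoking_fraction —
    the table behind load-ranked mutagen-exposure plots.
    """
    by_sample = {p.sample_id: p for p in profiles}
    rows = []
    for sample in sorted(cohort.samples, key=lambda s: (cohort.atml[s], s)):
        profile = by_sample.get(sample)
        rows.append(
            {
                "sample_id": sample,
                "atml": cohort.atml[sample],
                "uv_fraction": profile.uv_fraction if profile else float("nan"),
                "smoking_fraction": profile.smoking_fraction if profile else float("nan"),
            }
        )
    frame = pd.DataFrame(rows)
    frame.insert(0, "rank", range(1, len(rows) + 1))
    return frame


def profiles_frame(profiles: Sequence[SignatureProfile]) -> pd.DataFrame:
    """Tidy profile table: sample_id, n_snv, one fraction column per class."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "n_snv": p.n_snv}
        row.update({c: p.fraction_by_class[c] for c in SUBSTITUTION_CLASSES})
        rows.append(row)
    return pd.DataFrame(rows)
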