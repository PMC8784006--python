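"""Survey-wide thresholds.

Every cut-off used by the pipeline lives in :class:`Config` so that a single
object documents (and lets the user override) the screening E-value, segment
mismatch tolerances, tandem-duplication criteria, promoter length, SSR minima
and the TPM classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping


@dataclass(frozen=True)
class Config:
    """All tunable thresholds of the dehydrin survey pipeline.

    Attributes
    ----------
    evalue_threshold:
        Maximum E-value for an external domain-search hit (HMMER/BLASTP style
        tables) to enter the candidate set.
    k_tolerance, y_tolerance, s_tolerance:
        Maximum mismatches allowed against the K-, Y- and S-segment consensus.
        The S tolerance applies to the fixed prefix/suffix, not the serine run.
    tandem_min_coverage, tandem_min_identity, tandem_max_distance_bp:
        Tandem-duplication criteria: alignable fraction of the longer gene
        (strict ``>``), aligned-column identity (strict ``>``) and chromosomal
        gap in bp (strict ``<``).
    match_score, mismatch_score, open_gap_score, extend_gap_score:
        Local-alignment scoring used for the tandem screen and similarity.
    group_min_similarity:
        Single-linkage threshold on normalised identity for homoeolog grouping.
    promoter_length_bp:
        Length of the upstream region extracted ahead of the translation start.
    ssr_min_repeats:
        Minimum perfect repeat count per SSR unit length (2..5).
    tpm_low, tpm_high:
        Expression bin cut-points: ``tpm < tpm_low`` is low, values in
        ``[tpm_low, tpm_high]`` are medium, ``> tpm_high`` is high.
    fold_threshold, delta_threshold:
        Up/down-regulation rule: fold change strictly above ``fold_threshold``
        and absolute TPM change strictly above ``delta_threshold``.
    pseudocount:
        Added denominator guard when the control TPM is zero.
    """

    evalue_threshold: float = 1e-20
    k_tolerance: int = 2
    y_tolerance: int = 1
    s_tolerance: int = 1
    tandem_min_coverage: float = 0.70
    tandem_min_identity: float = 0.70
    tandem_max_distance_bp: int = 500_000
    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -2.0
    extend_gap_score: float = -0.5
    group_min_similarity: float = 0.70
    promoter_length_bp: int = 1500
    ssr_min_repeats: Mapping[int, int] = field(
        default_factory=lambda: {2: 6, 3: 4, 4: 3, 5: 3}
    )
    tpm_low: float = 1.0
    tpm_high: float = 10.0
    fold_threshold: float = 1.0
    delta_threshold: float = 10.0
    pseudocount: float = 0.01

    def with_options(self, **kwargs) -> "Config":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = Config()


def load_config(path) -> Config:
    """Read a flat ``key = value`` file into a :class:`Config`.

    Lines starting with ``#`` and blank lines are ignored.  Values are parsed
    as int, then float, falling back to string.  ``ssr_min_repeats`` entries
    are written as ``ssr_min_repeats.2 = 6`` etc.
    """
    fields = {}
    ssr: dict[int, int] = dict(DEFAULT_CONFIG.ssr_min_repeats)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("ssr_min_repeats."):
                ssr[int(key.split(".", 1)[1])] = int(value)
                continue
            if key not in Config.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
            for cast in (int, float):
                try:
                    value = cast(value)
                    break
                except ValueError:
                    continue
            fields[key] = value
    fields["ssr_min_repeats"] = ssr
    return Config(**fields)
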