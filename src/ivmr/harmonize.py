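"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS can report the same variant on different effect alleles or on
opposite strands.  Harmonization expresses both effects on the exposure's
effect allele: a swapped outcome record has its beta negated and its
frequency complemented; a strand-discordant record is complemented first.
Palindromic variants (A/T or C/G) cannot be strand-resolved from alleles
alone and are removed by default, as is standard; an optional ``infer``
policy keeps those whose allele frequencies on both sides agree and sit
far from 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sumstats import SummaryDataset, SummaryStatRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: maximum minor-allele frequency at which ``infer`` trusts a palindrome
INFER_MAF_MAX = 0.42

ACTION_KEPT = "kept_as_is"
ACTION_FLIPPED = "flipped_outcome"
ACTION_REMOVED_PALINDROMIC = "removed_palindromic"
ACTION_REMOVED_INCOMPATIBLE = "removed_incompatible"

_RETAINED_ACTIONS = frozenset({ACTION_KEPT, ACTION_FLIPPED})


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP on a shared effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    f_stat: float | None = None
    action: str = ACTION_KEPT

    @property
    def retained(self) -> bool:
        return self.action in _RETAINED_ACTIONS


@dataclass
class HarmonizeLog:
    """Join and per-pair dispositions for one harmonization run."""

    n_exposure: int = 0
    n_outcome: int = 0
    matched: list[str] = field(default_factory=list)
    lost_at_outcome: list[str] = field(default_factory=list)
    removed_palindromic: list[str] = field(default_factory=list)
    removed_incompatible: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.matched) - len(self.removed_palindromic) - len(self.removed_incompatible)


def is_palindromic(a1: str, a2: str) -> bool:
    """True when the allele pair is A/T or C/G (strand-ambiguous)."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _f_stat(rec: SummaryStatRecord) -> float:
    return (rec.beta / rec.se) ** 2


def _build(exp: SummaryStatRecord, out_se: float, out_beta, out_eaf, action) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out_beta,
        se_out=out_se,
        eaf_exp=exp.eaf,
        eaf_out=out_eaf,
        f_stat=_f_stat(exp),
        action=action,
    )


def harmonize_pair(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    policy: str = "remove",
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair (same snp_id).

    ``policy`` governs palindromic SNPs: ``"remove"`` drops them
    unconditionally; ``"infer"`` keeps those whose effect-allele
    frequencies identify the strand (MAF below ``INFER_MAF_MAX`` on both
    sides), orienting by frequency agreement.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    if policy not in ("remove", "infer"):
        raise ValueError(f"unknown palindrome policy {policy!r}")

    ea_e, oa_e = exp.effect_allele, exp.other_allele
    ea_o, oa_o = out.effect_allele, out.other_allele

    def finish(beta_out, eaf_out, action):
        return _build(exp, out.se, beta_out, eaf_out, action)

    if is_palindromic(ea_e, oa_e):
        # outcome must carry the same (strand-ambiguous) pair at all
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return finish(out.beta, out.eaf, ACTION_REMOVED_INCOMPATIBLE)
        if policy == "remove" or exp.eaf is None or out.eaf is None:
            return finish(out.beta, out.eaf, ACTION_REMOVED_PALINDROMIC)
        # infer: allele labels are uninformative, use frequencies
        maf_e = min(exp.eaf, 1 - exp.eaf)
        maf_o = min(out.eaf, 1 - out.eaf)
        if maf_e >= INFER_MAF_MAX or maf_o >= INFER_MAF_MAX:
            return finish(out.beta, out.eaf, ACTION_REMOVED_PALINDROMIC)
        # nominal alignment by labels, then frequency check
        if ea_o == ea_e:
            beta, eaf, action = out.beta, out.eaf, ACTION_KEPT
        else:
            beta, eaf, action = -out.beta, None if out.eaf is None else 1 - out.eaf, ACTION_FLIPPED
        if (exp.eaf - 0.5) * (eaf - 0.5) < 0:
            # frequencies disagree: labels were on opposite strands
            beta, eaf = -beta, 1 - eaf
            action = ACTION_FLIPPED if action == ACTION_KEPT else ACTION_KEPT
        return finish(beta, eaf, action)

    if (ea_o, oa_o) == (ea_e, oa_e):
        return finish(out.beta, out.eaf, ACTION_KEPT)
    if (ea_o, oa_o) == (oa_e, ea_e):
        return finish(-out.beta, None if out.eaf is None else 1 - out.eaf, ACTION_FLIPPED)

    # try the strand complement before giving up
    ca, cb = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
    if (ca, cb) == (ea_e, oa_e):
        return finish(out.beta, out.eaf, ACTION_KEPT)
    if (ca, cb) == (oa_e, ea_e):
        return finish(-out.beta, None if out.eaf is None else 1 - out.eaf, ACTION_FLIPPED)

    return finish(out.beta, out.eaf, ACTION_REMOVED_INCOMPATIBLE)


def harmonize_datasets(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    policy: str = "remove",
) -> tuple[list[HarmonizedInstrument], HarmonizeLog]:
    """Inner-join on snp_id and harmonize each pair.

    Returns the retained instruments ordered by snp_id and a log recording
    exposure SNPs absent from the outcome (no proxy search is attempted)
    and per-pair removals.
    """
    log = HarmonizeLog(n_exposure=len(exposure), n_outcome=len(outcome))
    outcome_by_id = {r.snp_id: r for r in outcome.records}
    retained: list[HarmonizedInstrument] = []
    for exp_rec in sorted(exposure.records, key=lambda r: r.snp_id):
        out_rec = outcome_by_id.get(exp_rec.snp_id)
        if out_rec is None:
            log.lost_at_outcome.append(exp_rec.snp_id)
            continue
        log.matched.append(exp_rec.snp_id)
        inst = harmonize_pair(exp_rec, out_rec, policy=policy)
        if inst.action == ACTION_REMOVED_PALINDROMIC:
            log.removed_palindromic.append(inst.snp_id)
        elif inst.action == ACTION_REMOVED_INCOMPATIBLE:
            log.removed_incompatible.append(inst.snp_id)
        else:
            retained.append(inst)
    return retained, log
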