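"""Accounting for the primary-melanoma discovery cohort the platform targets.

The workflow was developed around a retrospective, treatment-naive primary
cutaneous melanoma cohort with known sentinel lymph node (sLN) status.  Of
the resections passing dermatopathology quality assessment, some were lost
to repeated heat-mediated antigen retrieval and bleaching; the remainder form
the analyzed cohort.  The arithmetic below ties the accounting to the
clinical characteristics table and is verified by :func:`verify_cohort_accounting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CohortAccounting:
    """Sample flow from quality assessment to the analyzed cohort."""

    qa_passed_sln_negative: int = 27
    qa_passed_sln_positive: int = 14
    excluded_tissue_loss: int = 13

    @property
    def qa_passed_total(self) -> int:
        return self.qa_passed_sln_negative + self.qa_passed_sln_positive

    @property
    def analyzed(self) -> int:
        return self.qa_passed_total - self.excluded_tissue_loss


#: Clinical characteristics of the analyzed cohort (counts per category).
COHORT_CHARACTERISTICS: dict[str, dict[str, int]] = {
    "sln_status": {"negative": 17, "positive": 11},
    "gender": {"male": 14, "female": 14},
    "tumor_stage": {"PT2": 11, "PT3": 11, "PT4": 6},
    "ulceration": {"no": 16, "yes": 10, "unknown": 2},
    "ln_stage": {"PN0": 17, "PN1": 6, "PN2": 4, "PN3": 1},
}


def verify_cohort_accounting(
    accounting: CohortAccounting | None = None,
    characteristics: dict[str, dict[str, int]] | None = None,
) -> dict:
    """Check that the sample accounting reproduces the analyzed cohort size
    and that every characteristics category sums to it."""
    accounting = accounting or CohortAccounting()
    characteristics = characteristics or COHORT_CHARACTERISTICS
    n = accounting.analyzed
    category_totals = {k: sum(v.values()) for k, v in characteristics.items()}
    consistent = all(total == n for total in category_totals.values())
    return {
        "qa_passed": accounting.qa_passed_total,
        "excluded_tissue_loss": accounting.excluded_tissue_loss,
        "analyzed": n,
        "category_totals": category_totals,
        "consistent": consistent,
    }
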