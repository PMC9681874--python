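"""PANSS total-score validation.

The scale has 30 items, each rated 1-7, split into positive (7 items),
negative (7 items) and general psychopathology (16 items) subscales.  The
admissible total range is therefore derived, not hard-coded: bounds are
``n_items * item_min`` and ``n_items * item_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DataIntegrityError

#: Item counts per subscale.
N_POSITIVE_ITEMS = 7
N_NEGATIVE_ITEMS = 7
N_GENERAL_ITEMS = 16


@dataclass(frozen=True)
class PanssScale:
    """Structural description of the symptom scale used for validation."""

    n_items: int = N_POSITIVE_ITEMS + N_NEGATIVE_ITEMS + N_GENERAL_ITEMS
    item_min: int = 1
    item_max: int = 7

    @property
    def min_total(self) -> int:
        return self.n_items * self.item_min

    @property
    def max_total(self) -> int:
        return self.n_items * self.item_max

    def subscale_range(self, n_subscale_items: int) -> tuple[int, int]:
        return n_subscale_items * self.item_min, n_subscale_items * self.item_max

    def validate_total(
        self,
        total: float,
        positive: float | None = None,
        negative: float | None = None,
    ) -> None:
        """Raise :class:`DataIntegrityError` if a total (and optional
        subscale scores) cannot arise from the item structure."""
        if math.isnan(total):
            return  # missing totals are handled by completer selection
        if not self.min_total <= total <= self.max_total:
            raise DataIntegrityError(
                f"PANSS total {total} outside admissible range "
                f"[{self.min_total}, {self.max_total}]"
            )
        for name, value, n_sub in (
            ("positive", positive, N_POSITIVE_ITEMS),
            ("negative", negative, N_NEGATIVE_ITEMS),
        ):
            if value is None or math.isnan(value):
                continue
            lo, hi = self.subscale_range(n_sub)
            if not lo <= value <= hi:
                raise DataIntegrityError(
                    f"PANSS {name} subscale {value} outside [{lo}, {hi}]"
                )
        if (
            positive is not None
            and negative is not None
            and not (math.isnan(positive) or math.isnan(negative))
        ):
            # remaining (general) items contribute at least item_min each
            floor = positive + negative + N_GENERAL_ITEMS * self.item_min
            if total < floor:
                raise DataIntegrityError(
                    f"PANSS total {total} below subscale-implied floor {floor}"
                )
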