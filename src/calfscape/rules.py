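"""Association-rule mining over itemised sample descriptions.

Each sample becomes a transaction: binarised taxa, median-discretised
phenotypes, an age item, and a "CTC" item marking antibiotic treatment.
Frequent itemsets come from a level-wise (a-priori) search with exact
support counts; rules are every antecedent/consequent split of a
frequent itemset that clears the confidence threshold, scored by
support, confidence and lift.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "TransactionSet",
    "RuleSet",
    "build_transactions",
    "mine_rules",
    "rules_about",
    "frequent_itemsets",
]

CTC_ITEM = "CTC"


@dataclass
class TransactionSet:
    """One item set per sample (items unique within a transaction)."""

    transactions: list[frozenset]
    sample_ids: Optional[list[str]] = None

    def __len__(self) -> int:
        return len(self.transactions)


@dataclass
class RuleSet:
    """Mined rules with exact support/confidence/lift."""

    rules: pd.DataFrame  # antecedent, consequent (frozensets), metrics

    _COLUMNS = ["antecedent", "consequent", "support", "confidence", "lift"]

    def __len__(self) -> int:
        return len(self.rules)

    @classmethod
    def empty(cls) -> "RuleSet":
        return cls(pd.DataFrame(columns=cls._COLUMNS))

    def to_tsv(self, path, header_comment: Optional[str] = None) -> None:
        out = self.rules.copy()
        for col in ("antecedent", "consequent"):
            out[col] = out[col].map(lambda s: " & ".join(sorted(s)))
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index=False)


def build_transactions(components, phenotypes: Optional[pd.DataFrame],
                       metadata: pd.DataFrame,
                       discretization: str = "median") -> TransactionSet:
    """Itemise samples: taxa presence, high/low phenotypes, age, treatment.

    ``components`` may be a ComponentMatrix or a 0/1 DataFrame of taxa;
    continuous phenotype columns are split at their per-variable median
    (values at or above the median read "high" — ties go high,
    deterministically).  CON (treated) samples carry the "CTC" item.
    """
    if discretization != "median":
        raise ValueError("only median discretization is implemented")
    if hasattr(components, "values"):
        table = components.values if isinstance(
            getattr(components, "values"), pd.DataFrame) else components
    else:
        table = components
    if hasattr(components, "component_kinds"):
        binary_cols = [c for c, k in zip(components.values.columns,
                                         components.component_kinds)
                       if k == "binary"]
        table = components.values[binary_cols]
    transactions = []
    ids = list(table.index.astype(str))
    medians = (phenotypes.median(axis=0)
               if phenotypes is not None else None)
    for sid in table.index:
        items = {str(c) for c in table.columns if table.at[sid, c] >= 1.0}
        if phenotypes is not None:
            for c in phenotypes.columns:
                level = ("high" if phenotypes.at[sid, c] >= medians[c]
                         else "low")
                items.add(f"{c}={level}")
        items.add(f"age={int(metadata.at[sid, 'day'])}d")
        if metadata.at[sid, "group"] == "CON":
            items.add(CTC_ITEM)
        transactions.append(frozenset(items))
    return TransactionSet(transactions, ids)


def _support_count(transactions: Sequence[frozenset],
                   itemset: frozenset) -> int:
    return sum(1 for t in transactions if itemset <= t)


def frequent_itemsets(transactions: Sequence[frozenset],
                      min_support: float,
                      max_len: Optional[int] = None
                      ) -> dict[frozenset, float]:
    """Level-wise (a-priori) frequent-itemset search with exact supports.

    ``max_len`` caps the itemset size (None = unbounded), which keeps the
    search tractable on dense transaction sets.
    """
    n = len(transactions)
    if n == 0:
        return {}
    items = sorted({i for t in transactions for i in t})
    supports: dict[frozenset, float] = {}
    current = []
    for it in items:
        s = _support_count(transactions, frozenset([it])) / n
        if s >= min_support:
            fs = frozenset([it])
            supports[fs] = s
            current.append(tuple([it]))
    k = 1
    while current:
        k += 1
        if max_len is not None and k > max_len:
            break
        # join step: extend sorted (k-1)-tuples sharing a (k-2)-prefix
        candidates = set()
        current_set = set(current)
        for a, b in combinations(current, 2):
            if a[:-1] == b[:-1]:
                cand = tuple(sorted(set(a) | set(b)))
                # prune: every (k-1)-subset must be frequent
                if all(tuple(sorted(set(cand) - {x})) in current_set
                       for x in cand):
                    candidates.add(cand)
        nxt = []
        for cand in sorted(candidates):
            fs = frozenset(cand)
            s = _support_count(transactions, fs) / n
            if s >= min_support:
                supports[fs] = s
                nxt.append(cand)
        current = nxt
    return supports


def mine_rules(transactions: TransactionSet | Sequence[frozenset],
               min_support: float = 0.2,
               min_confidence: float = 0.8,
               max_len: Optional[int] = None) -> RuleSet:
    """All rules A -> C with support(A|C) >= min_support and
    confidence >= min_confidence, from every split of each frequent
    itemset (optionally capped at ``max_len`` items).  Metrics are exact
    counts over the transactions; an empty result is a valid outcome,
    not an error.
    """
    if not (0.0 < min_support <= 1.0) or not (0.0 < min_confidence <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")
    txs = (transactions.transactions
           if isinstance(transactions, TransactionSet) else list(transactions))
    n = len(txs)
    supports = frequent_itemsets(txs, min_support, max_len=max_len)
    rows = []
    for itemset, s_full in supports.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                a = frozenset(ante)
                c = itemset - a
                s_a = supports.get(a)
                if s_a is None:  # cannot happen by anti-monotonicity
                    s_a = _support_count(txs, a) / n
                conf = s_full / s_a
                if conf >= min_confidence:
                    s_c = supports.get(c, _support_count(txs, c) / n)
                    rows.append({"antecedent": a, "consequent": c,
                                 "support": s_full, "confidence": conf,
                                 "lift": conf / s_c if s_c > 0 else 0.0})
    if not rows:
        return RuleSet.empty()
    df = pd.DataFrame(rows, columns=RuleSet._COLUMNS)
    df = _sort_rules(df)
    return RuleSet(df)


def _rule_key(row) -> tuple:
    return (" & ".join(sorted(row["antecedent"])),
            " & ".join(sorted(row["consequent"])))


def _sort_rules(df: pd.DataFrame) -> pd.DataFrame:
    keys = df.apply(_rule_key, axis=1)
    df = df.assign(_a=[k[0] for k in keys], _c=[k[1] for k in keys])
    df = df.sort_values(by=["lift", "support", "_a", "_c"],
                        ascending=[False, False, True, True],
                        kind="mergesort")
    return df.drop(columns=["_a", "_c"]).reset_index(drop=True)


def rules_about(rules: RuleSet, item: str) -> RuleSet:
    """Rules mentioning ``item`` in antecedent or consequent.

    Sorted by lift descending, then support descending, then
    lexicographically; filtering is idempotent.
    """
    df = rules.rules
    if df.empty:
        return RuleSet.empty()
    mask = df.apply(lambda row: item in row["antecedent"]
                    or item in row["consequent"], axis=1)
    sub = df[mask].reset_index(drop=True)
    if sub.empty:
        return RuleSet.empty()
    return RuleSet(_sort_rules(sub))
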