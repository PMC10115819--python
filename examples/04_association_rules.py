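"""Screen for items associated with antibiotic treatment.

Itemises every sample (taxa presence, high/low phenotypes, age,
treatment flag), mines association rules with the a-priori search and
lists the rules involving the treatment item.
"""

from calfscape import (build_transactions, generate_study, mine_rules,
                       preprocess_study, rules_about)

study = generate_study(n_animals=12, seed=7)
components, _ = preprocess_study(study.abundance, study.chemicals,
                                 study.metadata)
transactions = build_transactions(components, study.physiology,
                                  study.metadata)
print(f"transactions: {len(transactions)}, "
      f"mean items per sample: "
      f"{sum(len(t) for t in transactions.transactions) / 36:.1f}")

ruleset = mine_rules(transactions, min_support=0.2, min_confidence=0.8,
                     max_len=2)
ctc_rules = rules_about(ruleset, "CTC")
print(f"pairwise rules mined: {len(ruleset)}; involving CTC: "
      f"{len(ctc_rules)}")
for _, row in ctc_rules.rules.head(5).iterrows():
    print(f"  {{{', '.join(sorted(row.antecedent))}}} -> "
          f"{{{', '.join(sorted(row.consequent))}}}  "
          f"supp={row.support:.2f} conf={row.confidence:.2f} "
          f"lift={row.lift:.2f}")
print("-> lift > 1 marks item combinations over-represented among "
      "treated (or untreated) samples relative to independence.")
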