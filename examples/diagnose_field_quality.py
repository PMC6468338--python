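"""Data-quality diagnostics for the packaged Ugandan field data.

For every town the report gives each distributor's share of capture 2 that
was a recapture, flags towns where one distributor out-recaptured the other
by more than 10 percentage points (a symptom of unequal effort or
non-random sampling), and lists arithmetic inconsistencies in the
transcribed counts.
"""

from crcpse import diagnose, estimate_town, load_uganda_summaries

for s in load_uganda_summaries():
    estimates = {d: estimate_town(s, d) for d in ("def1", "def2")}
    r = diagnose(s, estimates)
    shares = " ".join(f"{d}={v:.2f}" for d, v in r.distributor_shares.items())
    flag = "IMBALANCED" if r.imbalance_flag else "balanced  "
    bands = r.prevalence_flags["def2"]
    print(f"{r.town:<10}{r.population:<5}{flag}  shares: {shares:<18}"
          f"refusal rate {r.refusal_rate:.2f}  prevalence(def2): {bands}")
    for note in r.notes:
        print(f"           note: {note}")

print()
print("Shares are per-distributor recaptures / capture-2 total. An imbalance")
print("flag means the shares differ by >0.10, so the two capture-2 teams did")
print("not sample comparably. Prevalence bands compare the implied population")
print("share against published reference ranges (FSW 0.1-12.0%, MSM 3-5%).")
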