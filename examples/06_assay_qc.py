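"""Enhancer-assay quality control: the positivity rule and screen summary.

Lens expression from the minimal promoter marks successfully injected
embryos; a region is positive when more than half of those embryos show a
reproducible non-lens pattern, seen in at least 10 individual fish.
"""

from crmscan import call_activity, ontology_coverage, summarize_screen
from crmscan.assay import InjectionExperiment

experiments = [
    InjectionExperiment("regionA", n_alive=100, n_lens=46, n_specific=30),
    InjectionExperiment("regionB", n_alive=80, n_lens=20, n_specific=9),
    InjectionExperiment("regionC", n_alive=60, n_lens=40, n_specific=20),
]
for exp in experiments:
    call = call_activity(exp)
    print(f"{exp.region_id}: injection rate {call.injection_rate:.0%}, "
          f"specific rate {call.specific_rate:.1%} "
          f"-> {'POSITIVE' if call.positive else 'negative'}")
# regionB fails the >=10-fish rule despite a 45% rate; regionC fails the
# strict >50% rule at exactly one half.

screen = [InjectionExperiment(f"r{i:02d}", 80, 46, 30) for i in range(19)]
screen.append(InjectionExperiment("r19", 80, 46, 9))
summary = summarize_screen([call_activity(e) for e in screen])
print(f"screen: {summary['n_positive']}/{summary['n_tested']} regions "
      f"positive = {summary['pct_positive']:.0f}%")

vocabulary = [f"term{i:02d}" for i in range(32)]
lines = {"lineA": vocabulary[:11], "lineB": vocabulary[8:20]}
coverage = ontology_coverage(lines, vocabulary)
print(f"reporter lines label {coverage['n_labeled']} of "
      f"{coverage['n_vocabulary']} vocabulary terms = {coverage['pct']}%")
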