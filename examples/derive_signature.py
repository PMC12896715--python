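"""Derive the 37-gene EMT signature from the packaged gene tables.

Intersects the diagnostic table (genes deregulated in breast tumors vs
normal tissue, Welch screen) with the prognostic table (genes coherently
significant across DMFS/OS/RFS optimal-cutpoint survival screens) and
keeps direction-concordant genes: up-regulated & hazardous, or
down-regulated & protective.
"""

import emtsig as es

diagnostic = es.load_diagnostic_fixture()
prognostic = es.load_prognostic_fixture()
entries = es.derive_signature(diagnostic, prognostic)

up_worse = [e.gene for e in entries if e.klass == "up_worse"]
down_better = [e.gene for e in entries if e.klass == "down_better"]
discordant = [e.gene for e in entries if not e.concordant]

print(f"diagnostic table: {len(diagnostic)} genes; prognostic table: {len(prognostic)} genes")
print(f"overlap: {len(entries)} genes, {len(up_worse) + len(down_better)} concordant")
print(f"up-regulated & worse prognosis ({len(up_worse)}): {', '.join(up_worse)}")
print(f"down-regulated & better prognosis ({len(down_better)}): {', '.join(down_better)}")
print(f"discordant, kept for audit ({len(discordant)}): {', '.join(sorted(discordant))}")
# The concordant set is the signature: genes whose tumor deregulation and
# survival association point the same way.
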