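# Case scenario (synthetic reconstruction authored for this package; not original patient data)
id: 0026
name: Claire Davenport
description: This young woman is on a twice daily insulin regimen, injecting a biphasic preparation which has a premixed 30% to 70% ratio of short versus intermediate acting insulin. While this does not permit quite as much flexibility in selecting a dose - it does save on having to mix insulin in the syringe. Use the simulator to see what would happen if you switched this woman onto other biphasic preparations with, say, premixed 10/90, 20/80, 40/60, or 50/50 percent constituents.
weight: 56 kg
meal: 07:45 30
meal: 12:30 40
meal: 15:30 10
meal: 18:30 40
meal: 21:45 15
insulin: Mixtard 30/70
injection: 08:00 16
injection: 18:00 10
rtg: normal
ccr: normal
hepatic: normal
peripheral: normal
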