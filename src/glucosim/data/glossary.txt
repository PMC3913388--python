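Glossary
--------
BG (blood glucose): sugar concentration in blood, in mmol/L or mg/dL
  (18 mg/dL per mmol/L).
Plasma insulin: insulin concentration measured in blood (mU/L); here it all
  comes from injections, since the simulated patients secrete none.
Active insulin: the effect-compartment insulin that actually drives glucose
  uptake and hepatic balance; it lags behind plasma insulin.
HbA1c: glycosylated haemoglobin (%), a medium-term marker of average BG;
  estimated here from the simulated 24-h mean.
RTG (renal threshold of glucose): the BG level above which glucose spills
  into the urine.
CCR (creatinine clearance rate): used to estimate the glomerular filtration
  rate, which scales renal glucose loss.
NHGB (net hepatic glucose balance): the liver's signed glucose flux -
  production at low insulin, uptake at high insulin and glucose.
Short/intermediate/long-acting insulin: absorption-speed classes typified
  by Actrapid, NPH/Lente and UltraLente preparations.
Biphasic (premixed) insulin: a fixed-ratio mix of short- and
  intermediate-acting insulin in one injection (e.g. 30/70).
Periodic steady state: the 24-h profile reached when the same daily meals
  and injections repeat until the day closes on itself.
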