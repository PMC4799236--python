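# Annual medical-care consumer price index used to express costs in
# target-year dollars. Values approximate the published US medical-care CPI
# series (1982-84 = 100); deployments substitute the official table.
target_year: 2011
values:
  2006: 336.2
  2007: 351.1
  2008: 364.1
  2009: 375.6
  2010: 388.4
  2011: 400.3
  2012: 414.9
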