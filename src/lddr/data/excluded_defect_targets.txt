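# Components excluded from carcinogenic-defect searches (template).
# One component name per line.  Populate from the published exclusion
# list when working with the transcribed full network; the entry below
# is the package's own default (lesions do not mutate).
DSBs_late
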