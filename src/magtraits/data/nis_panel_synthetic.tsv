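name	siderophore	photolabile	membrane_bound
petrobactin_synthetase	petrobactin	true	false
vibrioferrin_synthetase	vibrioferrin	true	false
rhizoferrin_synthetase	rhizoferrin	true	false
aerobactin_synthetase	aerobactin	false	false
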