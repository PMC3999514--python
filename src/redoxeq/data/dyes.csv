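name,synonyms,E_m_mV,n,band_center_nm,band_width_nm
toluidine blue O,TBO;toluidine blue;tolonium chloride,34,2,628,28
"2,6-dichlorophenolindophenol","DCPIP;DCIP;dichlorophenolindophenol;disodium 2,6-dichlorophenolindophenol",217,2,604,28
Nile blue,Nile blue A,-116,2,634,30
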