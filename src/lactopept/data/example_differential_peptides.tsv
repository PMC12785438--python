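sequence	status	parent
RTPEVDDEALE	up	beta_LG
KEMPFPK	up	beta_CN
EPVLGPVR	up	beta_CN
YPFPGPIH	up	beta_CN
PFPGPIHNSLPQ	up	beta_CN
YQEPVLGPV	up	beta_CN
YVEELKPTPEG	up	beta_CN
NIPPLTQTPVVVPPFLQPEV	up	beta_CN
KGLDIQK	up	beta_LG
PFPGPIHN	up	beta_CN
DIPNPIGSENS	down	alphaS1_CN
HQPLPPTVMFPPQS	down	beta_CN
EMPFPKYPVE	down	beta_CN
EAESISSSEEIVPNSVEQ	down	alphaS1_CN
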