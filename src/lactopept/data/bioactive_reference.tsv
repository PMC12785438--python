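sequence	functions	parent	reference
TPEVDDEALEK	Antimicrobial;Antioxidant;DPP-IV Inhibitory	beta_LG	B26;B27;B28;B29;B30
TPEVDKEALE	Antimicrobial;Antioxidant;DPP-IV Inhibitory	beta_LG	B26;B27;B28;B29;B30
TPEVDKEALEK	Antimicrobial;Antioxidant;DPP-IV Inhibitory	beta_LG	B26;B27;B28;B29;B30
EMPFPK	Antimicrobial;ACE-inhibitory;Increase mucin secretion	beta_CN	B31;B32;B33;B34
HKEMPFPK	Antimicrobial;ACE-inhibitory;Increase mucin secretion	beta_CN	B31;B32;B33;B34
EPVLGPVRGP	Immunomodulatory;Antioxidant;ACE-inhibitory;Antithrombotic	beta_CN	B35;B36;B37;B38
YQEPVLGPVR	Immunomodulatory;Antioxidant;ACE-inhibitory;Antithrombotic	beta_CN	B35;B36;B37;B38
VYPFPGPI	Immunomodulatory;Increase mucin secretion;Opioid;ACE-inhibitory;Antianxiety;Antioxidant	beta_CN	B39;B40;B41;B42;B43;B44;B45;B46;B47
YPFPGPIP	Immunomodulatory;Increase mucin secretion;Opioid;ACE-inhibitory;Antianxiety;Antioxidant	beta_CN	B39;B40;B41;B42;B43;B44;B45;B46;B47
YPFPGPI	Immunomodulatory;Increase mucin secretion;Opioid;ACE-inhibitory;Antianxiety;Antioxidant	beta_CN	B39;B40;B41;B42;B43;B44;B45;B46;B47
PFTGPIPNSLPQ	Antimicrobial	beta_CN	B29
YQEPVLGP	Immunomodulatory;Antioxidant;ACE-inhibitory	beta_CN	B35;B36;B48;B49;B50
YQEPVLGPVRG	Immunomodulatory;Antioxidant;ACE-inhibitory	beta_CN	B35;B36;B48;B49;B50
YQEPVLGPVR	Immunomodulatory;Antioxidant;ACE-inhibitory	beta_CN	B35;B36;B48;B49;B50
LYQEPVLGPVR	Immunomodulatory;Antioxidant;ACE-inhibitory	beta_CN	B35;B36;B48;B49;B50
YVEELKPTPEGDL	Antioxidant	beta_CN	B51
NIPPLTQTPVVVPPFLQ	ACE-inhibitory	beta_CN	B52
GLDIQK	ACE-inhibitory;Cholesterol regulation	beta_LG	B31;B53
PFPGPIPN	ACE-inhibitory	beta_CN	B54
FSDIPNPIGSE	Antioxidant	alphaS1_CN	B55
FSDIPNPIGSEN	Antioxidant	alphaS1_CN	B55
HQPHQPLPPTVMFPPQ	Immunomodulatory;ACE-inhibitory	beta_CN	B50
MPFPKYPVEP	ACE-inhibitory	beta_CN	B52
QMEAESISSSEEIVPNSVEQK	Immunomodulatory	alphaS1_CN	B56
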