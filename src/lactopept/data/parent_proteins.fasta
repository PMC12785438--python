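>beta_CN Beta-casein, Bos taurus, mature chain (209 aa, A2 variant, UniProt P02666)
RELEELNVPGEIVESLSSSEESITRINKKIEKFQSEEQQQTEDELQDKIHPFAQTQSLVY
PFPGPIPNSLPQNIPPLTQTPVVVPPFLQPEVMGVSKVKEAMAPKHKEMPFPKYPVEPFT
ESQSLTLTDVENLHLPLPLLQSWMHQPHQPLPPTVMFPPQSVLSLSQSKVLPVPQKAVPY
PQRDMPIQAFLLYQEPVLGPVRGPFPIIV
>alphaS1_CN Alpha-S1-casein, Bos taurus, mature chain (199 aa, variant B, UniProt P02662)
RPKHPIKHQGLPQEVLNENLLRFFVAPFPEVFGKEKVNELSKDIGSESTEDQAMEDIKQM
EAESISSSEEIVPNSVEQKHIQKEDVPSERYLGYLEQLLRLKKYKVPQLEIVPNSAEERL
HSMKEGIHAQQKEPMIGVNQELAYFYPELFRQFYQLDAYPSGAWYYVPLGTQYTDAPSFS
DIPNPIGSENSEKTTMPLW
>alphaS2_CN Alpha-S2-casein, Bos taurus, mature chain (207 aa, variant A, UniProt P02663)
KNTMEHVSSSEESIISQETYKQEKNMAINPSKENLCSTFCKEVVRNANEEEYSIGSSSEE
SAEVATEEVKITVDDKHYQKALNEINQFYQKFPQYLQYLYQGPIVLNPWDQVKRNAVPIT
PTLNREQLSTSEENSKKTVDMESTEVFTKKTKLTEEEKNRLNFLKKISQRYQKFALPQYL
KTVYQHQKAMKPWIQPKTKVIPYVRYL
>kappa_CN Kappa-casein, Bos taurus, mature chain (169 aa, variant A, UniProt P02668)
QEQNQEQPIRCEKDERFFSDKIAKYIPIQYVLSRYPSYGLNYYQQKPVALINNQFLPYPY
YAKPAAVRSPAQILQWQVLSNTVPAKSCQAQPTTMARHPHPHLSFMAIPPKKNQDKTEIP
TINTIASGEPTSTPTTEAVESTVATLEDSPEVIESPPEINTVQVTSTAV
>beta_LG Beta-lactoglobulin, Bos taurus, mature chain (162 aa, variant B, UniProt P02754)
LIVTQTMKGLDIQKVAGTWYSLAMAASDISLLDAQSAPLRVYVEELKPTPEGDLEILLQK
WENGECAQKKIIAEKTKIPAVFKIDALNENKVLVLDTDYKKYLLFCMENSAEPEQSLACQ
CLVRTPEVDDEALEKFDKALKALPMHIRLSFNPTQLEEQCHI
>alpha_LA Alpha-lactalbumin, Bos taurus, mature chain (123 aa, variant B, UniProt P00711)
EQLTKCEVFRELKDLKGYGGVSLPEWVCTTFHTSGYDTQAIVQNNDSTEYGLFQINNKIW
CKDDQNPHSSNICNISCDKFLDDDLTDDIMCVKKILDKVGINYWLAHKALCSEKLDQWLC
EKL
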