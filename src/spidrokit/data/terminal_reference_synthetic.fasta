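>NTD_MaSp kind=NTD family=MaSp
MNWSTRLALSILAVLCTQSLAAQANTPWSSKANADAFINSFISAASNTGSFSQDQMEDMS
LIGNTLMAAMDNMGGRITPSKLQALDMAFASSVAEIAASEGGDLGVTTNAIADALTSAFY
QTTGVVNSRFISEIRSLIGMFAQASANDV
>NTD_TuSp kind=NTD family=TuSp
MNWTARFTLSLLVVLCAQSVSGQAKTPWENPAHAEAFIQNFLQNVSSSGAFTADQLDDMS
VISNTIMSSMDQMSSSVKTASQLQALNMAFASSMAELVIAENADLSSTTRAVADSLSSAF
LQTTGSVNQQFVNEISSLINMFAQVSSSSV
>CTD_MaSp1 kind=CTD family=MaSp1
SRLSSQSASERVSSAVSSLVSSYPTGPAHLSNAISVVVSSVSAGTWGSSGCDKAVNGLLE
VITATIHVLNYASFKQVNSSYVGVAASKCGHSVYQALA
>CTD_MaSp2 kind=CTD family=MaSp2
SFEHSFCASDRMSSAVSSLVSYGMTNNYSLECCVFYVVSQVSMSCPWSSREDVLVQALIT
VQTALIHVKGSMSIGQVNSSSRGQSAPIYGQSVYRRLS
>CTD_MaSp4 kind=CTD family=MaSp4
KRLSSPSYSVRVSSAKSSLVSSGPRNPASWSNHIQSVVMQVSASNKGSDGCDVRHQALLH
VIDELIHVNASACCGQVNSSSVGQSPHIVGQSNYRDLS
>CTD_MaSp5 kind=CTD family=MaSp5
SKHSIPSSSQNVDSAGLSLDASGPTNPACGSNDISQFVSQASLSNPGSSGCDVLVQALLE
VITCLIALLASWAIMQVKSSSVKQSASIVGDSCYHKGS
>CTD_TuSp kind=CTD family=TuSp
IRLAYPTSFNKSKSHAWTLLSSGPTKHDSLADAISSLFSTAMSQWGQYSPGYGNELLHTL
THLLQPFSQTSWPFDQDLLNKVNELITQFSHHMQDM
>CTD_Flag kind=CTD family=Flag
HRLASYTSLARISKHASTLLFSQPTKRFRHRDKHYFSCSTQMSQMGAYSPGYLHALLHTL
TTLDQVFSQTSGFNGLRLNNQVNELITMFSHHMNDS
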