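>synthetic_LanB_like synthetic stand-in reference for a class I dehydratase; not a real NisB sequence
SPTNSIWGADIAMFTKNCRYSPYWLFCLFMYMFQNPPAGAWSEKGCKGHRVFQDNIFWVV
WYAKDPHHKRSFGTKYRHFIQMWAQPDHFKHRFDRELDQSGWYAFYTMMPYQHCWFGTWW
YHEQHYYDCASHITMATNNPMRLMCYKWVIGYEYNGGEAQKKDPPQSPENRSIIEWAQVD
KYEPVMESKPIHEDFYAYKHYFKVALELSTVHHDCPIRRRKMITIEIPHWGMYGMNPYDF
RYYRYTMGLQRREHIRGDEPWKFLYMCHALEFHGADIFFMYTTPFLFAHCKWCETDALQY
>synthetic_LanC_like synthetic stand-in reference for a class I cyclase; not a real NisC sequence
CTKQVGLSSIRCNSCPTIIWNEGCAKHDRAYNVIGGQYVQEAMPTIMICMQEDEFLIRWD
GKALKEIRIILTQGEEIHHNHVVITIGVMQGEIRIFSSLSPEALTFEETNGETAVTCINW
PRHPKYENVNRNFSFFIFLPDWDNEPAVKPTHQMFYYHCEYRIRQSRKIRFRSTQASPWW
HGAEYKDENPYSENVNCDHWVMFHPFFNPTLMAAWFSQMHSALQCCMHHVPWKGCQKCQY
>synthetic_LanM_like synthetic stand-in reference for a class II bifunctional synthetase; not a real LanM sequence
AKIVAICVWKHSWQSPDWHNTVANGQGRVRYMGMRYGTDRPSWDNLATPNYFCKEYVTIV
GKLEVHNYDQFNQWPMWWGWDFLSNCLGNWEAGQLGMIACTKDCFMLIAHTGKIMHERWR
EEAHDQVCDYMDMIEHGTNMSRLYTDHQNAHPFTECKVTEREPLVLVVYSTKFHKQTSLR
CERNWWSVGCNDPEYVRRQWWPRAYSPRTYTNSKVIPVCMQETRWQVCLRSKQDLNVWYK
HRAYSLLAEAISTPPMHEKRIGDHIPNKEWRRKECHWWNCFMIRVQLSPMPKWQLVWNDK
ERYCDIAMCYFGTSYALAGW
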