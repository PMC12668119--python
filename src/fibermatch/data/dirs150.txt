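0.110760984626 -0.0959190368962 0.989207532647
-0.304179433393 0.0482575289481 0.95139165605
0.279662953203 0.0272480025228 0.959711508196
-0.0654182194089 -0.222113665038 0.972823712896
-0.121872908933 0.18607411666 0.974947904853
0.460797394495 -0.303925764997 0.833843444897
-0.46778739728 -0.0887192850208 0.879376960929
0.253617929018 0.236059264171 0.938058617507
-0.0224013322313 -0.416009027808 0.909084522526
-0.14920790816 0.38284036494 0.911685392619
0.463012612678 -0.0547155358449 0.884661251914
0.120425952122 -0.541585715863 0.831975061182
0.103986274801 0.576632720087 0.810358908619
0.415420526005 -0.548135130372 0.725929518222
-0.639989838291 0.218024308288 0.73680282836
0.596471347662 0.282773052247 0.751173303799
-0.523855183779 -0.44286428005 0.727631071275
-0.238807170437 0.667078229646 0.705675400507
0.711010885171 -0.266168469595 0.650859329626
-0.637839721182 -0.00287376023902 0.770163769328
0.222691652658 0.430223733457 0.874823391895
0.0189510683504 -0.699079313259 0.714792956584
-0.600002785854 0.435245470643 0.671236200791
0.748103248765 0.17689937065 0.639568715503
-0.41699858474 -0.639689237821 0.645685573124
-0.156310444553 0.817202193871 0.554750051154
0.665609914228 -0.50897165387 0.545812511434
-0.777158503242 0.0838645246558 0.623691752666
0.529697854411 0.492409129887 0.690618151974
-0.0734562527877 -0.824092188735 0.561672719109
-0.439187496283 0.575662282228 0.689729860111
0.752329351807 -0.042891024604 0.657389463269
-0.693612222802 -0.354962099058 0.626820542589
0.290131433888 0.812985413478 0.504854898502
0.341447010947 -0.752599095672 0.563035114277
-0.698915694964 0.501421595725 0.509993367284
0.837806499844 0.277038056954 0.470457419771
-0.288643305479 -0.799651359049 0.5265384565
-0.490080347193 0.128419180864 0.86216574235
0.959944297443 -0.0526068932386 -0.275208031478
-0.833741402847 -0.255652854064 0.489404629511
0.499055925515 0.757069416462 0.421650426142
0.267735332295 -0.879061638174 0.394421637504
-0.632746697777 0.69206928986 0.347378344871
0.943456012697 -0.0692981915488 0.324173584295
-0.654812524123 -0.65440807527 0.378114571623
0.0644903371763 0.83492336634 0.546574760441
0.639126273556 -0.664593385989 0.387082985611
-0.845742706168 0.360280744796 0.393595045564
0.770475938443 0.484224523673 0.414600336413
-0.364550127525 -0.866777490132 0.340293971623
-0.271941906523 0.884531063953 0.379015034502
0.899798877332 -0.286960767095 0.328657113875
-0.880680005486 -0.356095985906 0.312407389091
0.362069368285 0.878585648962 0.311437040165
0.389033919532 -0.897029649288 0.209738927603
-0.873361684518 0.45597986781 0.171235884579
0.911030979615 0.403989131768 0.0825550458541
-0.413249721283 -0.901753146787 0.126751450167
-0.191810213083 0.963440992533 0.187056932681
0.744766727736 -0.638817357929 0.19296347962
-0.994345906832 -0.0587272261693 0.0884722016945
0.667130563717 0.669441938618 0.326778673988
-0.0225532162613 -0.979065132468 0.202293892202
-0.574509106912 0.800942195241 0.168614607781
0.96630095328 -0.210625557531 0.147984263369
-0.787456236803 -0.560477451076 0.256471639671
0.219265854733 0.958868363384 0.180260774016
0.487890358928 -0.872683329154 0.0196673506562
-0.987743719606 0.144225439035 0.0596771908972
0.80672088488 0.590931447467 -0.00119928863697
-0.381731436245 -0.921528687817 -0.0711757550913
-0.289353480816 0.957139326244 -0.012604495103
0.937090171122 -0.348935416061 -0.0102998351981
-0.887343443507 -0.444865360893 0.12131126882
0.56820476243 0.822795146207 -0.012308343928
0.07659907322 -0.997015792383 0.00959644310805
-0.82875470205 0.559382971225 -0.0160104757208
0.973313226088 0.205102052971 0.102929644855
-0.69171269793 -0.712481329731 -0.11791479257
0.146742251926 0.989150866516 -0.00687566512318
0.667606981287 -0.744106660416 0.0246210572706
-0.992318078889 0.000514612035862 -0.12371162227
0.694860418469 0.706389386477 -0.134844479001
-0.0134200052181 -0.982339866104 -0.186623393287
-0.577774086046 0.788366656884 -0.21131758045
0.937708711011 -0.258703785504 -0.23189377883
-0.809335274729 -0.546528940306 -0.215133750228
0.230869152524 0.95531204311 -0.184603181721
0.390272449414 -0.90270532078 -0.18113674134
-0.882669927645 0.435278583323 -0.177274797224
0.960590770808 0.256138671962 -0.107973847593
-0.532249454299 -0.820850282398 -0.207160160953
-0.18603317051 0.960717875897 -0.205943736009
0.740554535164 -0.655267062029 -0.149010260944
-0.941320626649 -0.142920814653 -0.305759903494
0.5501579186 0.795166175026 -0.255023564984
0.0664301787283 -0.922232262951 -0.380886708255
-0.787006152422 0.507925952199 -0.350189296142
0.94120446038 0.154083028336 -0.300653594921
-0.614542729799 -0.591423146595 -0.522068860327
-0.0594928154522 0.916639046362 -0.395263789884
0.462134306648 -0.806168441176 -0.369491985124
-0.85123218012 0.149113246379 -0.503159035775
0.758354715984 0.466676381169 -0.455094803314
-0.14686179315 -0.916172175054 -0.372907708917
-0.466453128402 0.791889838923 -0.394121760392
0.773340973401 -0.544065063814 -0.32547956187
-0.893522062354 -0.349058397491 -0.28244744507
0.487000287723 0.736306636338 -0.469769365798
-0.15275870853 -0.911458391807 0.381979550464
0.22814014892 0.369371184783 -0.900842383718
0.878439966283 0.0465868560185 -0.47557637713
-0.425032260615 -0.675287064567 -0.602772724885
-0.1389295777 0.810038509588 -0.569680775017
0.546370707142 -0.647316474506 -0.531470067088
-0.867449879885 -0.0643784184919 -0.493341793406
0.601886137646 0.560192323542 -0.56913762655
-0.200690890836 -0.714177522207 -0.670577089609
-0.513262139284 0.642438030011 -0.56906533366
0.881366575852 -0.161232531869 -0.444068721751
-0.699761495244 -0.39359180181 -0.596170565628
0.210103507575 0.695857779411 -0.686759395231
0.360344925564 -0.752074859765 -0.551846844631
-0.79422554523 0.356546481209 -0.492016656265
0.753941067585 0.133586106905 -0.643216618761
-0.332440324958 -0.566418656738 -0.754091065881
-0.239083511293 0.657661858885 -0.714366820335
0.758201066044 -0.297812885773 -0.58003329949
-0.618671980612 -0.0673095078461 -0.78276076202
0.331468019087 0.515934532659 -0.789899050723
0.0245367494432 -0.716612586129 -0.69703970427
-0.573446817991 0.416092782871 -0.705709248188
0.600511862112 0.224325776804 -0.767504690099
-0.419156656831 -0.368415921876 -0.829805643234
0.120544381125 0.566827431604 -0.814969763218
0.309711060574 -0.48348894089 -0.818729200038
-0.604060459238 0.15928654278 -0.780857707187
0.476428124723 -0.350553383833 -0.806305504791
-0.0474128225502 -0.349351766318 -0.935791305596
-0.298701603613 0.433308975228 -0.850306229535
0.322209215063 -0.258838484825 -0.910595333012
-0.448781176183 -0.161978099341 -0.878839320489
0.422669205517 0.304404995654 -0.853632439243
0.0939980045717 -0.554965981391 -0.826545301018
-0.312075078127 0.19240919413 -0.930369737054
0.274411801154 0.162290166902 -0.947818582385
-0.0789606408022 -0.126340457301 -0.988839373232
-0.149090782912 0.310646505613 -0.938760186097
0.098106530877 0.018761415153 -0.994999054221
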